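"""Mixture-model reconstruction of a metagenome's domain profile.

The observed domain-hit distribution ``y`` is approximated by a convex
combination of reference signatures,

    y  ≈  ŷ = Σ_i w_i x_i ,      w_i ≥ 0,  Σ_i w_i = 1,

where each ``x_i`` is the domain profile of a taxonomically labelled
reference.  Under the generative reading — every domain hit is drawn i.i.d.
from the mixture density p(j) = Σ_i w_i x_ij — the weights are maximum
likelihood mixture proportions and are estimated by EM with fixed
components.  The log-likelihood

    L(w) = Σ_j y_j log Σ_i w_i x_ij

is concave in ``w`` on the simplex, so the EM fixed point reached from the
uniform start is a global maximizer (up to non-identifiability when columns
are collinear).

Model quality is summarised by the *fraction of domain hits unexplained*
(FDU), half the Manhattan distance between ``y`` and ``ŷ``; on unit-sum
vectors this is the Bray-Curtis dissimilarity.  Taxon abundances are read
off by summing the weights of the references carrying each taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    DomainProfile,
    RANKS,
    SignatureMatrix,
    TaxonomicProfile,
    TaxonomyTable,
    _fixed_point_normalize,
    require_aligned,
)
from .errors import (
    DomainmixError,
    FitDegenerateError,
    InvalidProfileError,
)

__all__ = [
    "FitOptions",
    "MixtureFit",
    "em_fit",
    "log_likelihood",
    "fdu",
    "bray_curtis",
    "aggregate_weights",
    "renormalize_subset",
]

#: Allowed deviation of a weight vector from the probability simplex.
SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs for the EM fit.

    max_iter
        Hard cap on EM updates (default 10 000).
    rel_tol
        Stop when the log-likelihood change per update falls below
        ``rel_tol * max(1, |L|)`` (default 1e-9).
    init
        ``None`` for the uniform start (recommended: the objective is
        concave, so the optimum does not depend on it) or an explicit
        simplex vector of length K.
    epsilon_floor
        Smallest mixture density used inside logarithms, guarding the
        likelihood against -inf on families a current iterate assigns zero
        mass.
    """

    max_iter: int = 10_000
    rel_tol: float = 1e-9
    init: np.ndarray | None = None
    epsilon_floor: float = 1e-300

    def __post_init__(self):
        if int(self.max_iter) < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be > 0")


@dataclass(frozen=True)
class MixtureFit:
    """Result of one mixture fit."""

    signature_ids: tuple[str, ...]
    weights: np.ndarray
    reconstruction: DomainProfile
    loglik_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    fdu: float
    unsupported_mass: float

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def weight_of(self, signature_id: str) -> float:
        return float(self.weights[self.signature_ids.index(signature_id)])

    def weights_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_ids, self.weights.tolist()))


def _check_simplex(weights: np.ndarray, k: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (k,):
        raise InvalidProfileError(f"expected {k} weights, got shape {w.shape}")
    if np.any(w < -SIMPLEX_TOL) or abs(w.sum() - 1.0) > SIMPLEX_TOL:
        raise InvalidProfileError(
            f"weights are off the probability simplex (sum={w.sum()!r})"
        )
    return np.clip(w, 0.0, None)


def _supported_restriction(profile: DomainProfile, refs: SignatureMatrix):
    """Restrict y to observed families carried by at least one reference.

    Families observed in the metagenome but absent from every reference
    would pin the likelihood at -inf; they are excluded from the likelihood
    (their total is reported as ``unsupported_mass``) but kept in the FDU.
    """
    y = profile.values
    observed = y > 0
    ref_support = refs.matrix.sum(axis=1) > 0
    supported = observed & ref_support
    unsupported_mass = float(y[observed & ~ref_support].sum())
    if not np.any(supported):
        raise FitDegenerateError(unsupported_mass)
    yr = y[supported]
    yr = yr / yr.sum()
    return supported, yr, unsupported_mass


def log_likelihood(
    profile: DomainProfile,
    refs: SignatureMatrix,
    weights,
    epsilon_floor: float = 1e-300,
) -> float:
    """Mixture log-likelihood L(w) = Σ_j y'_j log Σ_i w_i x_ij.

    ``y'`` is the observed profile restricted to families supported by at
    least one reference and renormalized, as used by :func:`em_fit`.
    """
    require_aligned(profile, refs)
    profile.require_normalized()
    w = _check_simplex(weights, refs.n_signatures)
    supported, yr, _ = _supported_restriction(profile, refs)
    p = refs.matrix[supported] @ w
    return float(yr @ np.log(np.maximum(p, epsilon_floor)))


def em_fit(
    profile: DomainProfile,
    refs: SignatureMatrix,
    opts: FitOptions | None = None,
) -> MixtureFit:
    """Estimate mixture weights by EM with fixed components.

    Each update computes responsibilities r_ij = w_i x_ij / Σ_k w_k x_kj and
    re-weights, w_i ← Σ_j y'_j r_ij, which in matrix form is one pass of

        p = X'w ;   w ← w ⊙ (X'ᵀ (y'/p)) ,

    over the supported-family restriction X', y'.  The update preserves the
    simplex and never decreases L.  Deterministic given inputs and options.
    """
    opts = opts or FitOptions()
    require_aligned(profile, refs)
    profile.require_normalized()
    supported, yr, unsupported_mass = _supported_restriction(profile, refs)

    X = np.ascontiguousarray(refs.matrix[supported])
    k = refs.n_signatures
    if opts.init is None:
        w = np.full(k, 1.0 / k)
    else:
        w = _check_simplex(opts.init, k)
        w = w / w.sum()

    trace: list[float] = []
    converged = False
    n_iter = 0
    ll_prev = None
    for _ in range(opts.max_iter):
        p = X @ w
        np.maximum(p, opts.epsilon_floor, out=p)
        ll = float(yr @ np.log(p))
        trace.append(ll)
        if ll_prev is not None and abs(ll - ll_prev) <= opts.rel_tol * max(
            1.0, abs(ll_prev)
        ):
            converged = True
            break
        ll_prev = ll
        w = w * (X.T @ (yr / p))
        s = w.sum()
        if s != 1.0:  # guard float drift off the simplex
            w = w / s
        n_iter += 1
    if not converged:
        # record the likelihood of the weights actually returned
        p = np.maximum(X @ w, opts.epsilon_floor)
        trace.append(float(yr @ np.log(p)))

    reconstruction = DomainProfile(
        refs.family_ids, _fixed_point_normalize(refs.matrix @ w)
    )
    return MixtureFit(
        signature_ids=refs.signature_ids,
        weights=w,
        reconstruction=reconstruction,
        loglik_trace=tuple(trace),
        n_iter=n_iter,
        converged=converged,
        fdu=fdu(profile, reconstruction),
        unsupported_mass=unsupported_mass,
    )


def fdu(observed: DomainProfile, reconstructed: DomainProfile) -> float:
    """Fraction of domain hits unexplained: half the L1 distance of y and ŷ.

    On unit-sum vectors the underpredicted mass Σ max(y−ŷ, 0) equals the
    overpredicted mass Σ max(ŷ−y, 0); the FDU is that common value, in
    [0, 1].
    """
    if observed.family_ids != reconstructed.family_ids:
        raise InvalidProfileError(
            "FDU requires both profiles on one ordered family universe"
        )
    observed.require_normalized()
    reconstructed.require_normalized()
    return float(0.5 * np.abs(observed.values - reconstructed.values).sum())


def bray_curtis(p: TaxonomicProfile, q: TaxonomicProfile) -> float:
    """Bray-Curtis dissimilarity of two unit-sum taxonomic profiles.

    Half the Manhattan distance over the union of taxa (absent taxa count
    as zero); symmetric, in [0, 1], zero iff the profiles are equal.
    """
    if p.rank != q.rank:
        raise InvalidProfileError(
            f"cannot compare profiles at different ranks ({p.rank!r} vs {q.rank!r})"
        )
    taxa = sorted(set(p.abundances) | set(q.abundances))
    pv = np.array([p.get(t) for t in taxa])
    qv = np.array([q.get(t) for t in taxa])
    return float(0.5 * np.abs(pv - qv).sum())


def aggregate_weights(
    fit: MixtureFit, taxonomy: TaxonomyTable, rank: str
) -> TaxonomicProfile:
    """Sum mixture weights per taxon at the requested rank.

    A reference with no annotation at ``rank`` (typical for metagenome-
    derived viral signatures, which carry only a superkingdom) contributes
    its weight to ``"unclassified <superkingdom>"``; total mass is conserved.
    """
    if rank not in RANKS:
        raise InvalidProfileError(f"unknown rank {rank!r}")
    missing = [s for s in fit.signature_ids if s not in taxonomy]
    if missing:
        raise DomainmixError(
            f"signature id(s) missing from the taxonomy table: {missing}"
        )
    abundances: dict[str, float] = {}
    for sid, w in zip(fit.signature_ids, fit.weights):
        rec = taxonomy[sid]
        taxon = rec.taxon_at(rank)
        if taxon is None:
            taxon = f"unclassified {rec.superkingdom}"
        abundances[taxon] = abundances.get(taxon, 0.0) + float(w)
    return TaxonomicProfile(rank, abundances)


def renormalize_subset(profile: TaxonomicProfile, taxa) -> TaxonomicProfile:
    """Restrict a taxonomic profile to selected taxa and rescale to unit sum.

    Used e.g. to compare archaea/bacteria fractions across tools on a common
    footing by forcing the two to sum to one.
    """
    taxa = sorted(set(taxa))
    if not taxa:
        raise InvalidProfileError("empty taxon subset")
    mass = sum(profile.get(t) for t in taxa)
    if mass <= 0:
        raise InvalidProfileError(
            f"no abundance mass on the requested subset {taxa}"
        )
    vals = _fixed_point_normalize(np.array([profile.get(t) for t in taxa]))
    return TaxonomicProfile(profile.rank, dict(zip(taxa, vals.tolist())))
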