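"""Core containers for protein-domain frequency profiling.

A metagenome is summarised by the relative frequencies of protein-domain
family hits (e.g. Pfam accessions) over all of its reads — its *domain
profile* ``y``.  Taxonomically labelled references (genomes or curated viral
metagenomes) are summarised the same way, giving the columns ``x_i`` of a
*signature matrix*.  Family identifiers are opaque strings; the containers
are dimension-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidProfileError

#: Canonical taxonomic ranks, highest first.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Tolerance for unit-sum invariants.
NORM_TOL = 1e-9

#: Valid provenance labels for a reference signature.
SOURCE_TYPES = ("genome", "metagenome")


def _as_float_vector(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidProfileError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise InvalidProfileError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass(frozen=True)
class DomainProfile:
    """Relative frequencies of domain-family hits.

    Parameters
    ----------
    family_ids
        Ordered, unique domain-family identifiers.
    values
        Nonnegative frequency (or count) per family.
    total_hits
        Number of domain hits underlying the frequencies, when known.
    """

    family_ids: tuple[str, ...]
    values: np.ndarray
    total_hits: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        vals = _as_float_vector(self.values)
        object.__setattr__(self, "values", vals)
        if len(self.family_ids) != vals.size:
            raise InvalidProfileError(
                f"{len(self.family_ids)} family ids but {vals.size} values"
            )
        if vals.size == 0:
            raise InvalidProfileError("empty profile")
        _check_unique(self.family_ids, "family ids")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InvalidProfileError("profile values must be finite and >= 0")
        if self.total_hits is not None:
            th = int(self.total_hits)
            if th < 0:
                raise InvalidProfileError("total_hits must be nonnegative")
            object.__setattr__(self, "total_hits", th)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.values.sum()) - 1.0) <= NORM_TOL

    def require_normalized(self, tol: float = 1e-6) -> None:
        s = float(self.values.sum())
        if abs(s - 1.0) > tol:
            raise InvalidProfileError(f"profile is not normalized (sum={s!r})")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.family_ids), name="value")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.family_ids, self.values.tolist()))


@dataclass(frozen=True)
class SignatureMatrix:
    """Column-stochastic matrix of reference signatures (families x references)."""

    family_ids: tuple[str, ...]
    signature_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        object.__setattr__(
            self, "signature_ids", tuple(str(s) for s in self.signature_ids)
        )
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise InvalidProfileError(f"signature matrix must be 2-D, got {mat.shape}")
        object.__setattr__(self, "matrix", mat)
        d, k = mat.shape
        if d != len(self.family_ids) or k != len(self.signature_ids):
            raise InvalidProfileError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.family_ids)} families x {len(self.signature_ids)} signatures"
            )
        if k == 0:
            raise InvalidProfileError("signature matrix has no columns")
        _check_unique(self.family_ids, "family ids")
        _check_unique(self.signature_ids, "signature ids")
        if np.any(mat < 0) or not np.all(np.isfinite(mat)):
            raise InvalidProfileError("signature values must be finite and >= 0")
        colsums = mat.sum(axis=0)
        if np.any(colsums == 0):
            bad = [self.signature_ids[i] for i in np.flatnonzero(colsums == 0)]
            raise InvalidProfileError(f"all-zero signature column(s): {bad}")
        if np.any(np.abs(colsums - 1.0) > NORM_TOL):
            bad = [
                self.signature_ids[i]
                for i in np.flatnonzero(np.abs(colsums - 1.0) > NORM_TOL)
            ]
            raise InvalidProfileError(
                f"signature column(s) not normalized within {NORM_TOL}: {bad}"
            )

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def column(self, signature_id: str) -> DomainProfile:
        try:
            k = self.signature_ids.index(signature_id)
        except ValueError:
            raise KeyError(signature_id) from None
        return DomainProfile(self.family_ids, self.matrix[:, k].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.family_ids), columns=list(self.signature_ids)
        )


@dataclass(frozen=True)
class DomainHitTable:
    """Raw per-read domain hits: (read_id, family_id) pairs plus a read total.

    ``total_reads`` counts every read in the dataset, hit or not; it is the
    denominator of the fraction of sequences unexplained (FSU).  A read may
    carry several hits.
    """

    hits: tuple[tuple[str, str], ...]
    total_reads: int

    def __post_init__(self):
        object.__setattr__(
            self, "hits", tuple((str(r), str(f)) for r, f in self.hits)
        )
        tr = int(self.total_reads)
        object.__setattr__(self, "total_reads", tr)
        n_hit_reads = len({r for r, _ in self.hits})
        if tr < 1:
            raise InvalidProfileError("total_reads must be a positive integer")
        if tr < n_hit_reads:
            raise InvalidProfileError(
                f"total_reads={tr} is smaller than the {n_hit_reads} distinct "
                "reads appearing in the hit list"
            )

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_hit_reads(self) -> int:
        return len({r for r, _ in self.hits})


@dataclass(frozen=True)
class LineageRecord:
    """Rank-structured lineage of one reference signature."""

    lineage: Mapping[str, str]
    source_type: str = "genome"

    def __post_init__(self):
        lin = {
            str(k): str(v)
            for k, v in dict(self.lineage).items()
            if v is not None and str(v) != ""
        }
        unknown = set(lin) - set(RANKS)
        if unknown:
            raise InvalidProfileError(f"unknown taxonomic rank(s): {sorted(unknown)}")
        if not lin.get("superkingdom"):
            raise InvalidProfileError("lineage must carry a non-empty superkingdom")
        object.__setattr__(self, "lineage", lin)
        if self.source_type not in SOURCE_TYPES:
            raise InvalidProfileError(
                f"source_type must be one of {SOURCE_TYPES}, got {self.source_type!r}"
            )

    @property
    def superkingdom(self) -> str:
        return self.lineage["superkingdom"]

    def taxon_at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise InvalidProfileError(f"unknown rank {rank!r}")
        return self.lineage.get(rank)


@dataclass(frozen=True)
class TaxonomyTable:
    """Mapping signature_id -> lineage + provenance."""

    records: Mapping[str, LineageRecord]

    def __post_init__(self):
        recs = {}
        for sid, rec in dict(self.records).items():
            if not isinstance(rec, LineageRecord):
                rec = LineageRecord(**rec)
            recs[str(sid)] = rec
        object.__setattr__(self, "records", recs)

    def __getitem__(self, signature_id: str) -> LineageRecord:
        return self.records[signature_id]

    def __contains__(self, signature_id: str) -> bool:
        return signature_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def signature_ids(self) -> tuple[str, ...]:
        return tuple(self.records)


@dataclass(frozen=True)
class TaxonomicProfile:
    """Estimated relative abundances at one taxonomic rank."""

    rank: str
    abundances: Mapping[str, float]

    def __post_init__(self):
        if self.rank not in RANKS:
            raise InvalidProfileError(f"unknown rank {self.rank!r}")
        ab = {str(t): float(v) for t, v in dict(self.abundances).items()}
        if not ab:
            raise InvalidProfileError("empty taxonomic profile")
        vals = np.array(list(ab.values()))
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InvalidProfileError("abundances must be finite and >= 0")
        if abs(vals.sum() - 1.0) > NORM_TOL:
            raise InvalidProfileError(
                f"abundances must sum to 1 within {NORM_TOL} (sum={vals.sum()!r})"
            )
        object.__setattr__(self, "abundances", ab)

    def get(self, taxon: str) -> float:
        return self.abundances.get(taxon, 0.0)

    def taxa(self) -> tuple[str, ...]:
        return tuple(self.abundances)


def _fixed_point_normalize(values: np.ndarray) -> np.ndarray:
    """Divide by the sum, iterating to a deterministic fixed point.

    A single division can leave the float sum one ulp away from 1.
    Iterating usually reaches sum == 1.0 bit-exactly in a step or two, but
    the iteration can also fall into a 2-cycle whose sums straddle 1 by one
    ulp each.  In that case the cycle member closest to unit sum (ties:
    smaller sum, then byte order) is returned.  Either way the result is a
    fixed point of this function, which makes normalization exactly
    idempotent.
    """
    out = np.asarray(values, dtype=float)
    seen: dict[bytes, int] = {}
    states: list[np.ndarray] = []
    for _ in range(32):
        s = out.sum()
        if s == 1.0:
            return out
        key = out.tobytes()
        if key in seen:
            cycle = states[seen[key] :]  # exactly one period of the cycle
            return min(
                cycle, key=lambda a: (abs(a.sum() - 1.0), a.sum(), a.tobytes())
            )
        seen[key] = len(states)
        states.append(out)
        out = out / s
    return out


def normalize_profile(raw) -> DomainProfile:
    """Turn raw per-family counts or weights into a unit-sum domain profile.

    ``raw`` may be a mapping family_id -> value, a ``DomainProfile``, or a
    pandas Series indexed by family id.  When the input consists of integer
    counts, their total is preserved as ``total_hits``.
    """
    total_hits = None
    if isinstance(raw, DomainProfile):
        ids, vals, total_hits = raw.family_ids, raw.values, raw.total_hits
    elif isinstance(raw, pd.Series):
        ids, vals = tuple(str(i) for i in raw.index), raw.to_numpy(dtype=float)
    elif isinstance(raw, Mapping):
        ids = tuple(str(k) for k in raw)
        vals = np.array([float(raw[k]) for k in raw])
    else:
        raise InvalidProfileError(
            f"cannot build a profile from {type(raw).__name__}"
        )
    vals = _as_float_vector(vals)
    if vals.size == 0:
        raise InvalidProfileError("empty profile")
    if np.any(vals < 0):
        raise InvalidProfileError("profile values must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise InvalidProfileError("profile has no positive value; cannot normalize")
    if total_hits is None and np.all(vals == np.round(vals)):
        total_hits = int(round(total))
    return DomainProfile(ids, _fixed_point_normalize(vals), total_hits=total_hits)


def align_families(
    profile: DomainProfile, refs: SignatureMatrix
) -> tuple[DomainProfile, SignatureMatrix]:
    """Reindex a profile and a signature matrix onto their union family universe.

    The union is sorted lexicographically; missing entries are zero-filled and
    no renormalization is applied, so observed mass outside every reference
    support is retained (it must stay visible to the model-fit error) and
    reference columns keep their unit sums.
    """
    union = sorted(set(profile.family_ids) | set(refs.family_ids))
    pos = {f: i for i, f in enumerate(union)}

    pvals = np.zeros(len(union))
    pvals[[pos[f] for f in profile.family_ids]] = profile.values
    out_profile = DomainProfile(union, pvals, total_hits=profile.total_hits)

    mat = np.zeros((len(union), refs.n_signatures))
    mat[[pos[f] for f in refs.family_ids], :] = refs.matrix
    out_refs = SignatureMatrix(union, refs.signature_ids, mat)
    return out_profile, out_refs


def require_aligned(profile: DomainProfile, refs: SignatureMatrix) -> None:
    """Raise unless the profile and matrix share one ordered family universe."""
    if profile.family_ids != refs.family_ids:
        raise AlignmentError(
            "profile and signature matrix are on different family universes; "
            "call align_families() first"
        )
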