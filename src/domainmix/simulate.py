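"""Synthetic fixtures with known ground truth.

The generators emulate the statistical structure the mixture model assumes:
reference signatures are sparse frequency vectors over a large family
universe (Dirichlet draws, one concentration per taxonomic group, so groups
differ in sparsity), a metagenome profile is a convex combination of those
signatures observed through multinomial sampling of finitely many domain
hits, and per-read hit tables carry a planted fraction of hit-less reads
(the FSU ground truth).  A separate generator plants contaminated samples
into a two-class signature-classification problem to exercise the vetting
procedure.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    DomainHitTable,
    DomainProfile,
    LineageRecord,
    SignatureMatrix,
    TaxonomyTable,
    _fixed_point_normalize,
    normalize_profile,
)
from .errors import DomainmixError, InvalidProfileError
from .selection import LabeledProfileSet

__all__ = [
    "GroupSpec",
    "SimulationSpec",
    "gen_reference_signatures",
    "gen_mixture_sample",
    "gen_hit_table",
    "gen_classification_dataset",
    "gen_random_fasta",
]


@dataclass(frozen=True)
class GroupSpec:
    """One taxonomic group of reference signatures.

    ``alpha`` is the symmetric Dirichlet concentration per family; smaller
    values give sparser, more idiosyncratic signatures (viral metagenome
    profiles are sparser than bacterial genome profiles).
    """

    superkingdom: str
    n_references: int
    alpha: float
    source_type: str = "genome"

    def __post_init__(self):
        if self.n_references < 0:
            raise DomainmixError("n_references must be >= 0")
        if not self.alpha > 0:
            raise DomainmixError("alpha must be > 0")


#: Default reference collection template: a bacteria-dominated mix with
#: archaeal, eukaryotic and (metagenome-derived) viral signatures, 20 in
#: total, with group-specific sparsity.
DEFAULT_GROUPS = (
    GroupSpec("Bacteria", 12, alpha=0.5),
    GroupSpec("Archaea", 3, alpha=0.4),
    GroupSpec("Eukaryota", 2, alpha=0.6),
    GroupSpec("Viruses", 3, alpha=0.2, source_type="metagenome"),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic profiling experiment."""

    n_families: int = 2000
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    true_weights: np.ndarray | None = None  # None: drawn Dirichlet(2) from seed
    n_hits: int = 100_000
    hit_probability: float = 0.7
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 2:
            raise DomainmixError("need at least 2 domain families")
        if self.n_references < 1:
            raise DomainmixError("need at least 1 reference signature")
        if not 0.0 <= self.hit_probability <= 1.0:
            raise DomainmixError("hit_probability must be in [0, 1]")
        if self.n_hits < 0:
            raise DomainmixError("n_hits must be >= 0")
        if self.true_weights is not None:
            w = np.asarray(self.true_weights, dtype=float)
            if w.shape != (self.n_references,) or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
                raise DomainmixError(
                    "true_weights must be a simplex vector of length "
                    f"{self.n_references}"
                )
            object.__setattr__(self, "true_weights", w)

    @property
    def n_references(self) -> int:
        return sum(g.n_references for g in self.groups)


_PHYLA_PER_GROUP = 3


def gen_reference_signatures(
    spec: SimulationSpec,
) -> tuple[SignatureMatrix, TaxonomyTable]:
    """Draw the reference collection: Dirichlet signature columns + lineages.

    Genome-type references carry a full synthetic lineage (phyla cycle
    within each superkingdom, species are unique); metagenome-type
    references carry the superkingdom only, as for viral metagenome
    signatures.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_families
    family_ids = [f"PF{i:05d}" for i in range(d)]
    columns = []
    sig_ids = []
    records: dict[str, LineageRecord] = {}
    for g in spec.groups:
        prefix = g.superkingdom[:3].lower()
        for j in range(g.n_references):
            sid = f"{prefix}{j:03d}"
            sig_ids.append(sid)
            columns.append(_fixed_point_normalize(rng.dirichlet(np.full(d, g.alpha))))
            if g.source_type == "metagenome":
                lineage = {"superkingdom": g.superkingdom}
            else:
                lineage = {
                    "superkingdom": g.superkingdom,
                    "phylum": f"{g.superkingdom}_phylum{j % _PHYLA_PER_GROUP}",
                    "class": f"{g.superkingdom}_class{j % _PHYLA_PER_GROUP}",
                    "order": f"{g.superkingdom}_order{j}",
                    "family": f"{g.superkingdom}_family{j}",
                    "genus": f"{g.superkingdom}_genus{j}",
                    "species": f"{g.superkingdom}_species{j}",
                }
            records[sid] = LineageRecord(lineage, source_type=g.source_type)
    matrix = np.column_stack(columns)
    return SignatureMatrix(family_ids, sig_ids, matrix), TaxonomyTable(records)


def draw_true_weights(spec: SimulationSpec) -> np.ndarray:
    """The planted mixture weights for a spec (explicit or seeded Dirichlet)."""
    if spec.true_weights is not None:
        return spec.true_weights
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 17]))
    return _fixed_point_normalize(rng.dirichlet(np.full(spec.n_references, 2.0)))


def gen_mixture_sample(
    refs: SignatureMatrix,
    true_weights,
    n_hits: int,
    seed=None,
    exact: bool = False,
) -> tuple[DomainProfile, np.ndarray]:
    """Observe the planted mixture through multinomial hit sampling.

    With ``exact=True`` the noise-free mixture Σ w*_i x_i itself is returned
    (``n_hits`` ignored); otherwise ``n_hits`` domain hits are drawn from
    the mixture categorical distribution and their relative frequencies
    returned, with ``total_hits`` recorded.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.shape != (refs.n_signatures,) or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
        raise DomainmixError("true_weights must be a simplex vector, one per signature")
    p = refs.matrix @ w
    if exact:
        return DomainProfile(refs.family_ids, _fixed_point_normalize(p)), w
    if n_hits < 1:
        raise DomainmixError("n_hits must be >= 1 unless exact=True")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_hits), p / p.sum())
    profile = normalize_profile(dict(zip(refs.family_ids, counts.tolist())))
    return profile, w


def gen_hit_table(
    profile: DomainProfile, n_reads: int, hit_probability: float, seed=None
) -> DomainHitTable:
    """Per-read hit table with planted FSU = 1 - hit_probability.

    Each read independently receives one domain hit with probability
    ``hit_probability``; the hit's family is drawn from the profile.
    """
    if n_reads < 1:
        raise DomainmixError("n_reads must be >= 1")
    if not 0.0 <= hit_probability <= 1.0:
        raise DomainmixError("hit_probability must be in [0, 1]")
    profile.require_normalized()
    rng = np.random.default_rng(seed)
    has_hit = rng.random(n_reads) < hit_probability
    n_hit = int(has_hit.sum())
    fam_idx = rng.choice(profile.n_families, size=n_hit, p=profile.values)
    hits = []
    hit_positions = np.flatnonzero(has_hit)
    for pos, fi in zip(hit_positions, fam_idx):
        hits.append((f"read{pos:07d}", profile.family_ids[int(fi)]))
    return DomainHitTable(tuple(hits), total_reads=n_reads)


def _tilted_means(n_families: int, separation: float) -> tuple[np.ndarray, np.ndarray]:
    """Two mean profiles at a requested symmetric-KL separation.

    The means tilt a uniform base up/down on complementary halves of the
    family universe; the tilt scale is solved by bisection so that
    sym-KL(m+, m-) equals ``separation`` (monotone in the tilt).
    """
    u = np.ones(n_families)
    u[n_families // 2 :] = -1.0

    def means(t):
        a = np.exp(0.5 * t * u)
        b = np.exp(-0.5 * t * u)
        return a / a.sum(), b / b.sum()

    def sym_kl(t):
        ma, mb = means(t)
        return float(np.sum((ma - mb) * (np.log(ma) - np.log(mb))))

    if separation < 0:
        raise DomainmixError("separation must be >= 0")
    if separation == 0:
        return means(0.0)
    lo, hi = 0.0, 1.0
    while sym_kl(hi) < separation:
        hi *= 2.0
        if hi > 1e3:
            raise DomainmixError("requested separation is unreachable")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if sym_kl(mid) < separation:
            lo = mid
        else:
            hi = mid
    return means(0.5 * (lo + hi))


def gen_classification_dataset(
    n_per_class: int,
    n_families: int,
    separation: float,
    n_flipped: int,
    seed=None,
    concentration: float = 5.0,
) -> tuple[LabeledProfileSet, tuple[str, ...]]:
    """Two Dirichlet sample classes with planted contaminated candidates.

    Class +1 ("vir") and class -1 ("mic") samples are drawn from Dirichlet
    distributions around two mean profiles separated by ``separation`` in
    symmetric KL.  ``n_flipped`` of the +1-labelled samples are actually
    drawn from the -1 distribution — planted contamination the vetting
    procedure should eliminate.  Only +1 samples are marked eligible.
    ``concentration`` scales within-class noise: the Dirichlet parameter is
    ``concentration * n_families * mean`` (≈ ``concentration`` per family).

    Returns the labelled set and the ground-truth ids of the planted flips.
    """
    if n_per_class < 2:
        raise DomainmixError("need at least 2 samples per class")
    if not 0 <= n_flipped < n_per_class:
        raise DomainmixError(
            "n_flipped must be smaller than n_per_class (a class of flips only "
            "is not a class)"
        )
    m_pos, m_neg = _tilted_means(n_families, separation)
    rng = np.random.default_rng(seed)
    alpha_pos = concentration * n_families * m_pos
    alpha_neg = concentration * n_families * m_neg

    pos_ids = tuple(f"vir{i:03d}" for i in range(n_per_class))
    neg_ids = tuple(f"mic{i:03d}" for i in range(n_per_class))
    flip_idx = rng.choice(n_per_class, size=n_flipped, replace=False)
    flipped = np.zeros(n_per_class, dtype=bool)
    flipped[flip_idx] = True

    rows = []
    for i in range(n_per_class):  # +1-labelled samples (flips drawn from -1)
        rows.append(rng.dirichlet(alpha_neg if flipped[i] else alpha_pos))
    for _ in range(n_per_class):  # -1 samples
        rows.append(rng.dirichlet(alpha_neg))
    profiles = np.array([_fixed_point_normalize(r) for r in rows])

    family_ids = tuple(f"PF{i:05d}" for i in range(n_families))
    labels = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)]).astype(int)
    eligible = labels == 1
    data = LabeledProfileSet(
        pos_ids + neg_ids, family_ids, profiles, labels, eligible
    )
    return data, tuple(pos_ids[i] for i in np.flatnonzero(flipped))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_random_fasta(n_seqs: int, length_range: tuple[int, int], seed=None):
    """Uniform-ACGT records with seeded lengths in [lo, hi]; deterministic."""
    lo, hi = int(length_range[0]), int(length_range[1])
    if not 1 <= lo <= hi:
        raise DomainmixError("length_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(int(n_seqs)):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        records.append(SeqRecord(Seq(seq), id=f"seq{i:04d}", description=""))
    return records
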