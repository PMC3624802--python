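"""Building reference signatures from genomes and hit tables.

Genomic and metagenomic domain profiles are only comparable when both are
estimated from short sequences, so genomes are cut into half-overlapping
400 bp fragments before (external) domain detection.  Very short phage
genomes do not support a stable frequency estimate and are removed by a
strict >100 kbp length filter.  The resulting per-reference hit tables are
turned into column-stochastic signatures, and per-dataset statistical
coverage is summarised by the fraction of sequences unexplained (FSU) — the
share of reads without any domain hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    DomainHitTable,
    DomainProfile,
    SignatureMatrix,
    TaxonomyTable,
    normalize_profile,
)
from .errors import DomainmixError, InvalidProfileError

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "ModelQuality",
    "fragment_sequences",
    "extract_fragment_records",
    "filter_min_length",
    "profile_from_hits",
    "fsu",
    "build_signature_matrix",
    "model_quality",
]

DEFAULT_FRAGMENT_LENGTH = 400
DEFAULT_MIN_GENOME_LENGTH = 100_000


@dataclass(frozen=True)
class FragmentSet:
    """Fragment coordinates: (source_id, start, end), 0-based half-open."""

    fragments: tuple[tuple[str, int, int], ...]
    fragment_length: int
    step: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "fragments",
            tuple((str(s), int(a), int(b)) for s, a, b in self.fragments),
        )
        for src, start, end in self.fragments:
            if not (0 <= start < end):
                raise ValueError(f"bad fragment interval ({src}, {start}, {end})")
            if end - start > self.fragment_length:
                raise ValueError(
                    f"fragment ({src}, {start}, {end}) exceeds fragment_length"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    def by_source(self, source_id: str) -> list[tuple[int, int]]:
        return [(a, b) for s, a, b in self.fragments if s == source_id]


@dataclass(frozen=True)
class ModelQuality:
    """Paired quality indices of one profiling run.

    ``fdu`` measures how well the mixture reconstructs the observed domain
    distribution; ``fsu`` measures how much of the dataset carried domain
    information at all.  Low/low is the trustworthy corner.
    """

    fsu: float
    fdu: float
    n_reads: int
    n_hits: int

    def __post_init__(self):
        for name in ("fsu", "fdu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def fragment_sequences(
    sequences: Iterable[SeqRecord],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    step: int | None = None,
    min_tail: int | None = None,
) -> FragmentSet:
    """Cut sequences into half-overlapping windows.

    Regular fragments start at 0, step, 2*step, ...; when the last regular
    fragment leaves >= ``min_tail`` bp uncovered, one extra fragment anchored
    at the sequence end (L - fragment_length, L) is emitted so no long tail
    of the genome goes unrepresented.  Sequences shorter than
    ``fragment_length`` but at least ``min_tail`` long yield one
    whole-sequence fragment; shorter ones are skipped (logged).

    Defaults: ``step = fragment_length / 2`` (half overlap; requires an even
    fragment length), ``min_tail = step``.
    """
    fragment_length = int(fragment_length)
    if fragment_length < 2:
        raise ValueError("fragment_length must be >= 2")
    if step is None:
        if fragment_length % 2 != 0:
            raise ValueError(
                "half-overlapping fragments need an even fragment_length; "
                "pass step explicitly for odd lengths"
            )
        step = fragment_length // 2
    step = int(step)
    if not 1 <= step <= fragment_length:
        raise ValueError("step must satisfy 1 <= step <= fragment_length")
    min_tail = step if min_tail is None else int(min_tail)

    frags: list[tuple[str, int, int]] = []
    n_records = 0
    for rec in sequences:
        n_records += 1
        L = len(rec.seq)
        if L >= fragment_length:
            n_full = (L - fragment_length) // step + 1
            last_end = 0
            for i in range(n_full):
                start = i * step
                frags.append((rec.id, start, start + fragment_length))
                last_end = start + fragment_length
            if L - last_end >= min_tail:
                frags.append((rec.id, L - fragment_length, L))
        elif L >= min_tail:
            frags.append((rec.id, 0, L))
        else:
            logger.info(
                "skipping %s: length %d below min_tail=%d", rec.id, L, min_tail
            )
    if n_records == 0:
        raise ValueError("no input sequences")
    return FragmentSet(tuple(frags), fragment_length=fragment_length, step=step)


def extract_fragment_records(
    sequences: Iterable[SeqRecord], fragset: FragmentSet
) -> list[SeqRecord]:
    """Materialise fragment sequences, ids ``<source_id>:<start>-<end>``."""
    by_id = {rec.id: rec for rec in sequences}
    out = []
    for src, start, end in fragset.fragments:
        rec = by_id[src]
        out.append(
            SeqRecord(
                Seq(str(rec.seq[start:end])),
                id=f"{src}:{start}-{end}",
                description="",
            )
        )
    return out


def filter_min_length(
    sequences: Iterable[SeqRecord], min_bp: int = DEFAULT_MIN_GENOME_LENGTH
) -> list[SeqRecord]:
    """Keep records strictly longer than ``min_bp``; order preserved."""
    return [rec for rec in sequences if len(rec.seq) > min_bp]


def profile_from_hits(hits: DomainHitTable) -> DomainProfile:
    """Relative frequency of each domain family among all hits.

    Counting is per hit, not per read: a read with several domain hits
    contributes each of them.
    """
    if hits.n_hits == 0:
        raise InvalidProfileError("hit table contains no hits; cannot profile")
    counts: dict[str, int] = {}
    for _, fam in hits.hits:
        counts[fam] = counts.get(fam, 0) + 1
    return normalize_profile({f: counts[f] for f in sorted(counts)})


def fsu(hits: DomainHitTable) -> float:
    """Fraction of sequences unexplained: reads without any domain hit.

    A read with several hits still counts once as explained.
    """
    return 1.0 - hits.n_hit_reads / hits.total_reads


def build_signature_matrix(
    hit_tables: Mapping[str, DomainHitTable], taxonomy: TaxonomyTable
) -> SignatureMatrix:
    """Assemble one signature column per reference over the union universe.

    References with an empty hit table are skipped with a warning; a
    reference without a taxonomy record is an error.
    """
    missing = [rid for rid in hit_tables if rid not in taxonomy]
    if missing:
        raise DomainmixError(
            f"reference id(s) missing from the taxonomy table: {missing}"
        )
    profiles: dict[str, DomainProfile] = {}
    for rid, table in hit_tables.items():
        if table.n_hits == 0:
            logger.warning("reference %s has no domain hits; skipped", rid)
            continue
        profiles[rid] = profile_from_hits(table)
    if not profiles:
        raise DomainmixError("no reference with domain hits; cannot build matrix")
    union = sorted({f for p in profiles.values() for f in p.family_ids})
    pos = {f: i for i, f in enumerate(union)}
    mat = np.zeros((len(union), len(profiles)))
    for k, (rid, prof) in enumerate(profiles.items()):
        mat[[pos[f] for f in prof.family_ids], k] = prof.values
    return SignatureMatrix(union, tuple(profiles), mat)


def model_quality(fit, hits: DomainHitTable) -> ModelQuality:
    """Bundle the FDU of a fit with the FSU of the underlying hit table."""
    return ModelQuality(
        fsu=fsu(hits), fdu=fit.fdu, n_reads=hits.total_reads, n_hits=hits.n_hits
    )
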