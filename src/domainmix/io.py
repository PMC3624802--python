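"""Plain-text (TSV) readers and writers for the domainmix formats.

All files are UTF-8, LF-terminated, tab-separated, unquoted.  Values are
written with 17 significant digits so a write/read round trip reproduces
every float bit-exactly.  Readers reject malformed input with the offending
line number.

Formats
-------
profile TSV
    optional ``#total_hits=<N>`` comment, then header ``family_id\tvalue``
    and one row per family.
signature TSV
    header ``family_id\t<sig_1>\t...``, one column per reference signature.
taxonomy TSV
    header ``signature_id\tsource_type\tsuperkingdom\t...\tspecies``; cells
    below superkingdom may be empty.
hit TSV
    ``#total_reads=<N>`` comment, header ``read_id\tfamily_id``, one row per
    domain hit (a read may appear several times).
labels TSV
    header ``sample_id\tlabel\teligible`` with labels ``+1``/``-1`` and
    eligibility ``1``/``0``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import (
    DomainHitTable,
    DomainProfile,
    LineageRecord,
    RANKS,
    SignatureMatrix,
    TaxonomicProfile,
    TaxonomyTable,
)
from .errors import ParseError

_FMT = "%.17g"

_TAXONOMY_HEADER = ("signature_id", "source_type") + RANKS


def _fmt(x: float) -> str:
    return _FMT % float(x)


def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    return lines


def _parse_float(cell: str, path, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric value {cell!r}") from None


# ---------------------------------------------------------------------------
# profiles

def read_profile_table(path) -> DomainProfile:
    lines = _read_lines(path)
    total_hits = None
    i = 0
    if lines and lines[0].startswith("#total_hits="):
        try:
            total_hits = int(lines[0].split("=", 1)[1])
        except ValueError:
            raise ParseError(path, 1, "malformed #total_hits comment") from None
        i = 1
    if i >= len(lines) or lines[i] != "family_id\tvalue":
        raise ParseError(path, i + 1, "expected header 'family_id<TAB>value'")
    ids: list[str] = []
    vals: list[float] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(cells)}")
        fam, val = cells
        if fam in seen:
            raise ParseError(path, lineno, f"duplicate family id {fam!r}")
        seen.add(fam)
        ids.append(fam)
        vals.append(_parse_float(val, path, lineno))
    if not ids:
        raise ParseError(path, len(lines) + 1, "profile table has no data rows")
    return DomainProfile(ids, np.array(vals), total_hits=total_hits)


def write_profile_table(profile: DomainProfile, path) -> None:
    out = []
    if profile.total_hits is not None:
        out.append(f"#total_hits={profile.total_hits}")
    out.append("family_id\tvalue")
    out.extend(
        f"{fam}\t{_fmt(v)}" for fam, v in zip(profile.family_ids, profile.values)
    )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# signature matrices

def read_signature_table(path) -> SignatureMatrix:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty signature table")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "family_id":
        raise ParseError(
            path, 1, "expected header 'family_id<TAB><sig_id_1><TAB>...'"
        )
    sig_ids = header[1:]
    if len(set(sig_ids)) != len(sig_ids):
        raise ParseError(path, 1, "duplicate signature ids in header")
    ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                path, lineno, f"expected {len(header)} columns, got {len(cells)}"
            )
        fam = cells[0]
        if fam in seen:
            raise ParseError(path, lineno, f"duplicate family id {fam!r}")
        seen.add(fam)
        ids.append(fam)
        rows.append([_parse_float(c, path, lineno) for c in cells[1:]])
    if not ids:
        raise ParseError(path, len(lines) + 1, "signature table has no data rows")
    return SignatureMatrix(ids, sig_ids, np.array(rows))


def write_signature_table(refs: SignatureMatrix, path) -> None:
    out = ["family_id\t" + "\t".join(refs.signature_ids)]
    for fam, row in zip(refs.family_ids, refs.matrix):
        out.append(fam + "\t" + "\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# taxonomy

def read_taxonomy_table(path) -> TaxonomyTable:
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != list(_TAXONOMY_HEADER):
        raise ParseError(
            path, 1, "expected header '" + "\\t".join(_TAXONOMY_HEADER) + "'"
        )
    records: dict[str, LineageRecord] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(_TAXONOMY_HEADER):
            raise ParseError(
                path,
                lineno,
                f"expected {len(_TAXONOMY_HEADER)} columns, got {len(cells)}",
            )
        sid, source_type, *taxa = cells
        if sid in records:
            raise ParseError(path, lineno, f"duplicate signature id {sid!r}")
        if not taxa[0]:
            raise ParseError(path, lineno, f"empty superkingdom for {sid!r}")
        try:
            records[sid] = LineageRecord(
                lineage={r: t for r, t in zip(RANKS, taxa) if t},
                source_type=source_type,
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if not records:
        raise ParseError(path, len(lines) + 1, "taxonomy table has no data rows")
    return TaxonomyTable(records)


def write_taxonomy_table(taxonomy: TaxonomyTable, path) -> None:
    out = ["\t".join(_TAXONOMY_HEADER)]
    for sid, rec in taxonomy.records.items():
        taxa = [rec.lineage.get(r, "") for r in RANKS]
        out.append("\t".join([sid, rec.source_type] + taxa))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# hit tables

def read_hit_table(path) -> DomainHitTable:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("#total_reads="):
        raise ParseError(path, 1, "expected leading '#total_reads=<N>' line")
    try:
        total_reads = int(lines[0].split("=", 1)[1])
    except ValueError:
        raise ParseError(path, 1, "malformed #total_reads value") from None
    if len(lines) < 2 or lines[1] != "read_id\tfamily_id":
        raise ParseError(path, 2, "expected header 'read_id<TAB>family_id'")
    hits = []
    for lineno, line in enumerate(lines[2:], start=3):
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(cells)}")
        hits.append((cells[0], cells[1]))
    return DomainHitTable(hits, total_reads=total_reads)


def write_hit_table(table: DomainHitTable, path) -> None:
    out = [f"#total_reads={table.total_reads}", "read_id\tfamily_id"]
    out.extend(f"{r}\t{f}" for r, f in table.hits)
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# labels (for signature selection)

def read_labels_table(path) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Return (sample_ids, labels ±1, eligible booleans)."""
    lines = _read_lines(path)
    if not lines or lines[0] != "sample_id\tlabel\teligible":
        raise ParseError(path, 1, "expected header 'sample_id<TAB>label<TAB>eligible'")
    ids: list[str] = []
    labels: list[int] = []
    eligible: list[bool] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(cells)}")
        sid, lab, elig = cells
        if sid in ids:
            raise ParseError(path, lineno, f"duplicate sample id {sid!r}")
        if lab not in {"+1", "1", "-1"}:
            raise ParseError(path, lineno, f"label must be +1 or -1, got {lab!r}")
        if elig not in {"0", "1"}:
            raise ParseError(path, lineno, f"eligible must be 0 or 1, got {elig!r}")
        ids.append(sid)
        labels.append(1 if lab in {"+1", "1"} else -1)
        eligible.append(elig == "1")
    if not ids:
        raise ParseError(path, len(lines) + 1, "labels table has no data rows")
    return tuple(ids), np.array(labels, dtype=int), np.array(eligible, dtype=bool)


def write_labels_table(sample_ids, labels, eligible, path) -> None:
    out = ["sample_id\tlabel\teligible"]
    for sid, lab, elig in zip(sample_ids, labels, eligible):
        out.append(f"{sid}\t{'+1' if lab > 0 else '-1'}\t{1 if elig else 0}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reports

def write_weights_table(fit, path) -> None:
    out = ["signature_id\tweight"]
    out.extend(
        f"{sid}\t{_fmt(w)}" for sid, w in zip(fit.signature_ids, fit.weights)
    )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def write_taxonomic_profile_table(profile: TaxonomicProfile, path) -> None:
    out = ["taxon\tabundance"]
    out.extend(f"{t}\t{_fmt(v)}" for t, v in profile.abundances.items())
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_taxonomic_profile_table(path, rank: str) -> TaxonomicProfile:
    lines = _read_lines(path)
    if not lines or lines[0] != "taxon\tabundance":
        raise ParseError(path, 1, "expected header 'taxon<TAB>abundance'")
    ab: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(cells)}")
        if cells[0] in ab:
            raise ParseError(path, lineno, f"duplicate taxon {cells[0]!r}")
        ab[cells[0]] = _parse_float(cells[1], path, lineno)
    return TaxonomicProfile(rank, ab)
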