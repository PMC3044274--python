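"""Reading and writing PSM tables and protein databases.

The canonical PSM table is a UTF-8 TSV with columns ``spectrum_id``,
``peptide``, ``evalue``, ``score`` and ``proteins`` (semicolon-separated
accessions).  ``evalue`` or ``score`` may be omitted but not both; a
missing score is derived from the E-value as -log10(E-value), so that
higher always means better.  ``proteins`` may be omitted when a protein
FASTA is supplied for substring mapping.

Peptide strings are stripped to plain uppercase residues on input:
modification annotations (lowercase letters, brackets, mass deltas) do
not change which proteins contain the peptide, and protein membership is
all the affinity graph uses.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, ContractError, RowError

logger = logging.getLogger(__name__)

_RESIDUE_RE = re.compile(r"^[A-Z]+$")

#: Columns of the canonical PSM table, in write order.
PSM_COLUMNS = ("spectrum_id", "peptide", "evalue", "score", "proteins")


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum pair with its initial score and protein set.

    The same peptide may appear in several records (identified by more
    than one spectrum); records stay distinct, keyed by ``psm_id``.
    """

    psm_id: int
    spectrum_id: str
    peptide: str
    initial_score: float
    evalue: float | None = None
    proteins: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not _RESIDUE_RE.match(self.peptide):
            raise ContractError(
                f"psm {self.psm_id}: peptide {self.peptide!r} is not a plain "
                "uppercase residue string"
            )
        if not math.isfinite(self.initial_score):
            raise ContractError(f"psm {self.psm_id}: initial_score is not finite")


@dataclass(frozen=True)
class ProteinEntry:
    """A protein database entry; ``is_decoy`` marks decoy accessions."""

    accession: str
    sequence: str
    is_decoy: bool = False


def strip_peptide(peptide: str) -> str:
    """Reduce a (possibly modified) peptide string to uppercase residues.

    Drops anything that is not an uppercase letter: bracketed mass
    deltas, lowercase modification tags, terminal markers like ``-`` or
    ``.`` flanking notation.
    """
    return re.sub(r"[^A-Z]", "", peptide)


def transform_score(evalue: float) -> float:
    """Map an E-value to the initial ranking score -log10(E-value).

    Strictly decreasing in the E-value, so smaller (better) E-values get
    larger scores.  Base 10 is the display convention for E-values; the
    base only rescales the score vector and is recorded in run metadata
    because regularization is not scale-invariant.
    """
    if evalue <= 0:
        raise ConfigError(f"E-value must be positive, got {evalue}")
    return -math.log10(evalue)


def read_psm_table(path: str | Path, decoy_pattern: str | None = None) -> list[PSMRecord]:
    """Read the canonical PSM TSV into a list of records.

    One record per data row, in file order; ``psm_id`` is the 0-based
    row index, so duplicate (spectrum_id, peptide) rows stay distinct.
    Requires ``spectrum_id``, ``peptide`` and at least one of ``score``
    / ``evalue``.  ``decoy_pattern`` is unused here (labels are applied
    at evaluation time) and accepted only for interface symmetry.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"PSM table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("spectrum_id", "peptide"):
        if col not in df.columns:
            raise ConfigError(f"PSM table {path} is missing required column {col!r}")
    has_score = "score" in df.columns
    has_evalue = "evalue" in df.columns
    if not (has_score or has_evalue):
        raise ConfigError(
            f"PSM table {path} needs a 'score' or an 'evalue' column; found neither"
        )

    records: list[PSMRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based, after the header
        evalue = _parse_float(getattr(row, "evalue", ""), "evalue", line) if has_evalue else None
        score = _parse_float(getattr(row, "score", ""), "score", line) if has_score else None
        if score is None:
            if evalue is None:
                raise RowError("neither score nor evalue given", line)
            score = transform_score(evalue)
        proteins = frozenset()
        if "proteins" in df.columns:
            cell = row.proteins.strip()
            if cell:
                proteins = frozenset(a for a in cell.split(";") if a)
        records.append(
            PSMRecord(
                psm_id=idx,
                spectrum_id=row.spectrum_id,
                peptide=strip_peptide(row.peptide),
                initial_score=score,
                evalue=evalue,
                proteins=proteins,
            )
        )
    return records


def _parse_float(cell: str, name: str, line: int) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowError(f"unparsable {name} value {cell!r}", line) from None


def filter_by_evalue(records: Sequence[PSMRecord], cutoff: float = 0.1) -> list[PSMRecord]:
    """Keep records with E-value <= cutoff (boundary inclusive), in order.

    All records must carry an E-value; requesting the filter on a table
    without E-values is a configuration error.
    """
    missing = [r.psm_id for r in records if r.evalue is None]
    if missing:
        raise ConfigError(
            f"E-value filter requested but {len(missing)} records carry no "
            f"E-value (first psm_id {missing[0]})"
        )
    return [r for r in records if r.evalue <= cutoff]


def read_fasta(path: str | Path, decoy_pattern: str = "DECOY_") -> list[ProteinEntry]:
    """Read a protein FASTA; flag decoys by accession pattern match.

    ``decoy_pattern`` is a regular expression anchored at the start of
    the accession (plain prefixes like ``DECOY_`` work as-is).
    Duplicate accessions are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"FASTA not found: {path}")
    pattern = re.compile(decoy_pattern)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ConfigError(f"duplicate accession in {path}: {rec.id!r}")
        seen.add(rec.id)
        entries.append(
            ProteinEntry(
                accession=rec.id,
                sequence=str(rec.seq).upper(),
                is_decoy=bool(pattern.match(rec.id)),
            )
        )
    return entries


def map_peptides_to_proteins(
    records: Sequence[PSMRecord], proteins: Sequence[ProteinEntry]
) -> list[PSMRecord]:
    """Assign each record the accessions of every protein containing its peptide.

    Membership is a plain substring scan of the stripped residue string
    (leucine and isoleucine are not equated).  Records whose peptide is
    found in no protein are dropped with a logged warning — they cannot
    take part in graph construction.
    """
    mapped: list[PSMRecord] = []
    for rec in records:
        hits = frozenset(p.accession for p in proteins if rec.peptide in p.sequence)
        if not hits:
            logger.warning(
                "psm %s (peptide %s) maps to no protein; dropping", rec.psm_id, rec.peptide
            )
            continue
        mapped.append(replace(rec, proteins=hits))
    return mapped


def write_psm_table(
    records: Sequence[PSMRecord],
    path: str | Path,
    new_scores: Sequence[float] | np.ndarray | None = None,
) -> None:
    """Write records back to the canonical TSV.

    With ``new_scores`` (one per record, in order) an extra
    ``regularized_score`` column is appended.  Floats are written with
    17 significant digits so a round trip reproduces them exactly.
    """
    if new_scores is not None and len(new_scores) != len(records):
        raise ContractError(
            f"{len(new_scores)} new scores for {len(records)} records"
        )
    cols = dict.fromkeys(PSM_COLUMNS, None)
    rows = []
    for rec in records:
        rows.append(
            {
                "spectrum_id": rec.spectrum_id,
                "peptide": rec.peptide,
                "evalue": _fmt(rec.evalue),
                "score": _fmt(rec.initial_score),
                "proteins": ";".join(sorted(rec.proteins)),
            }
        )
    df = pd.DataFrame(rows, columns=list(cols))
    if new_scores is not None:
        df["regularized_score"] = [_fmt(s) for s in new_scores]
    df.to_csv(path, sep="\t", index=False)


def _fmt(value: float | None) -> str:
    return "" if value is None else format(float(value), ".17g")
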