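"""Readers, writers and table filters for immunopeptidomics inputs.

Handles the external formats the pipeline touches: a FASTA proteome, TSV
peptide/PSM tables, HLA pseudosequence tables, external predictor score
tables and single-allelic reference sets.  Allele names are normalized to
the canonical ``HLA-A*02:01`` form on every read so downstream joins are
deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Ligand length window applied throughout the pipeline.
MIN_LENGTH = 8
MAX_LENGTH = 11


@dataclass(frozen=True)
class Proteome:
    """A set of protein sequences indexed by identifier.

    ``entries`` maps protein identifier to an uppercase amino-acid sequence.
    Identifiers are unique by construction; sequences containing letters
    outside the canonical 20-letter alphabet are listed in ``noncanonical``.
    """

    entries: Mapping[str, str]
    noncanonical: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, protein_id: str) -> str:
        return self.entries[protein_id]


@dataclass
class PeptideRecord:
    """One observed peptide with sample metadata and a PSM search score.

    ``log_prob`` is the search engine's -log10 p-value for the best PSM of
    this sequence in this sample.  Modification annotations are carried in
    ``extra['mod']``; ``sequence`` is always the plain residue string.
    """

    sequence: str
    sample_id: str
    log_prob: float
    extra: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class HLAAllele:
    """A normalized class-I allele name plus its binding-groove pseudosequence."""

    name: str
    pseudosequence: str


def is_canonical(sequence: str) -> bool:
    """True iff every residue is one of the 20 canonical amino acids."""
    return bool(sequence) and set(sequence) <= _CANONICAL_SET


def _strip_uniprot(header_token: str) -> str:
    # UniProt "sp|P01234|NAME_HUMAN" / "tr|...|..." collapses to the accession.
    parts = header_token.split("|")
    if len(parts) == 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_token


def read_fasta(path: str | Path) -> Proteome:
    """Read a FASTA proteome.

    The identifier is the header token before the first whitespace, with
    UniProt ``sp|ACC|NAME`` headers collapsed to the accession.  Sequences
    are uppercased.  An empty file yields an empty proteome with a warning.

    Raises
    ------
    ValueError
        If the file contains sequence data before any ``>`` header, naming
        the offending line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno} contains sequence data before any "
                    "FASTA header ('>') line"
                )
            break

    entries: dict[str, str] = {}
    noncanonical: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        protein_id = _strip_uniprot(record.id)
        seq = str(record.seq).upper()
        if not seq:
            logger.warning("skipping empty sequence for %s", protein_id)
            continue
        if protein_id in entries:
            raise ValueError(f"duplicate FASTA identifier: {protein_id}")
        entries[protein_id] = seq
        if not is_canonical(seq):
            noncanonical.add(protein_id)
    if not entries:
        logger.warning("no FASTA records read from %s", path)
    if noncanonical:
        logger.warning(
            "%d proteins contain noncanonical letters", len(noncanonical)
        )
    return Proteome(entries=entries, noncanonical=frozenset(noncanonical))


_ALLELE_RE = re.compile(
    r"""^ (?:HLA-)?              # optional prefix
         ([A-C])                 # class-I locus
         \*?                     # optional star
         (\d{2,3})               # allele group
         :?                      # optional colon
         (\d{2,3}) $             # protein field
    """,
    re.VERBOSE,
)


def normalize_allele_name(raw: str) -> str:
    """Normalize a class-I HLA allele name to ``HLA-A*02:01`` form.

    Accepts ``A*02:01``, ``HLA-A02:01``, ``A0201`` and the already-canonical
    form (idempotent).  Four-digit compact forms split 2+2; five-digit forms
    are ambiguous and rejected unless a separator disambiguates.
    """
    if not raw or not raw.strip():
        raise ValueError("empty allele name")
    text = raw.strip().upper().replace("HLA-", "", 1) if raw.strip().upper().startswith("HLA-") else raw.strip().upper()
    # Compact digits without separators: split four digits as 2+2.
    compact = re.fullmatch(r"([A-C])\*?(\d{4})", text)
    if compact:
        locus, digits = compact.groups()
        return f"HLA-{locus}*{digits[:2]}:{digits[2:]}"
    m = _ALLELE_RE.match(text)
    if m and (":" in text or "*" in text or re.fullmatch(r"[A-C]\d+:\d+", text)):
        locus, group, protein = m.groups()
        return f"HLA-{locus}*{int(group):02d}:{int(protein):02d}"
    raise ValueError(
        f"cannot parse allele name {raw!r}; accepted formats: 'HLA-A*02:01', "
        "'A*02:01', 'HLA-A02:01', 'A02:01', 'A0201'"
    )


def filter_psm_table(
    records: Iterable[PeptideRecord], min_log_prob: float = 1.3
) -> list[PeptideRecord]:
    """Apply the post-search PSM filters.

    Keeps a record iff its ``log_prob`` >= ``min_log_prob`` (boundary
    inclusive), its length is within the 8-11 residue window, and the
    sequence uses only canonical residues; then de-duplicates so that each
    (sample, sequence) pair keeps only its highest-scoring PSM.  Never
    raises; removal counts are logged.  Idempotent.
    """
    n_in = 0
    n_score = n_length = n_alphabet = 0
    best: dict[tuple[str, str], PeptideRecord] = {}
    for rec in records:
        n_in += 1
        if rec.log_prob < min_log_prob:
            n_score += 1
            continue
        if not (MIN_LENGTH <= len(rec.sequence) <= MAX_LENGTH):
            n_length += 1
            continue
        if not is_canonical(rec.sequence):
            n_alphabet += 1
            continue
        key = (rec.sample_id, rec.sequence)
        if key not in best or rec.log_prob > best[key].log_prob:
            best[key] = rec
    kept = list(best.values())
    logger.info(
        "PSM filter: %d in, %d kept (%d below log_prob, %d outside 8-11, "
        "%d noncanonical, %d duplicates)",
        n_in, len(kept), n_score, n_length, n_alphabet,
        n_in - n_score - n_length - n_alphabet - len(kept),
    )
    return kept


def read_peptides(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide TSV (sequence, sample_id, log_prob[, mod])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sequence", "sample_id", "log_prob"):
        if col not in df.columns:
            raise ValueError(f"peptide table {path} missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        extra = {}
        if "mod" in df.columns and isinstance(getattr(row, "mod", None), str):
            extra["mod"] = row.mod
        records.append(
            PeptideRecord(
                sequence=row.sequence.upper(),
                sample_id=row.sample_id,
                log_prob=float(row.log_prob),
                extra=extra,
            )
        )
    return records


def write_peptides(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "sample_id": r.sample_id,
            "log_prob": r.log_prob,
            "mod": r.extra.get("mod", ""),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[tuple[str, str, float]]:
    """Read an external predictor TSV with columns peptide/allele/score.

    Allele names are normalized; non-numeric scores reject the row with its
    1-based data row number in the error message.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("peptide", "allele", "score"):
        if col not in df.columns:
            raise ValueError(f"prediction table {path} missing column {col!r}")
    out: list[tuple[str, str, float]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {i}: score {row.score!r} is not numeric"
            ) from None
        out.append((row.peptide.upper(), normalize_allele_name(row.allele), score))
    return out


def write_predictions(
    records: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write (peptide, allele, score) rows; order preserved, round-trips."""
    df = pd.DataFrame(records, columns=["peptide", "allele", "score"])
    df.to_csv(path, sep="\t", index=False)


def read_pseudosequences(path: str | Path) -> dict[str, str]:
    """Read an allele -> pseudosequence table; all entries must share one length."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("allele", "pseudosequence"):
        if col not in df.columns:
            raise ValueError(f"pseudosequence table {path} missing column {col!r}")
    table = {
        normalize_allele_name(row.allele): row.pseudosequence.upper()
        for row in df.itertuples(index=False)
    }
    lengths = {len(p) for p in table.values()}
    if len(lengths) > 1:
        raise ValueError(
            f"pseudosequences in {path} have mixed lengths {sorted(lengths)}"
        )
    return table


def write_pseudosequences(table: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"allele": a, "pseudosequence": p} for a, p in table.items()]
    ).to_csv(path, sep="\t", index=False)


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a single-allelic reference set (peptide, allele[, source, year])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide", "allele"):
        if col not in df.columns:
            raise ValueError(f"reference table {path} missing column {col!r}")
    df = df.copy()
    df["peptide"] = df["peptide"].str.upper()
    df["allele"] = df["allele"].map(normalize_allele_name)
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce")
    return df
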