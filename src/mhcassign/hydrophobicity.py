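"""GRAVY hydropathy, anchor-weighted variants, and elution fold-change regression.

Class-I ligand recovery during C18 elution is biased by peptide
hydrophobicity, and the bias is dominated by the residues docking into the
MHC binding groove (the anchor positions, canonically P2 and the C-terminal
position of a 9mer).  This module computes the grand average of hydropathy
(GRAVY; Kyte-Doolittle by default), an anchor-weighted variant in which
anchor residues are counted twice, per-allele means over 9mer ligand sets,
between-condition fold changes of per-allele ligand counts, and the ordinary
least-squares regression linking per-allele hydrophobicity to those fold
changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy scale (the scale GRAVY is defined on).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Canonical class-I anchors of a 9mer: P2 and the C-terminal position.
DEFAULT_ANCHORS: frozenset[int] = frozenset({2, 9})


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of y on x: slope, intercept, R^2 and the slope's two-sided p."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def gravy(peptide: str, scale: Mapping[str, float] = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean per-residue hydropathy value."""
    if not peptide:
        raise ValueError("empty peptide")
    try:
        return sum(scale[aa] for aa in peptide) / len(peptide)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from None


def anchor_weighted_gravy(
    peptide: str,
    anchors: Iterable[int] = DEFAULT_ANCHORS,
    scale: Mapping[str, float] = KYTE_DOOLITTLE,
) -> float:
    """GRAVY with anchor-position residues counted twice; 9mers only.

    ``anchors`` are 1-based positions.  The result is a true mean over the
    duplicated multiset: (sum + anchor residues' sum) / (9 + n_anchors), so
    an empty anchor set reduces to plain ``gravy``.
    """
    if len(peptide) != 9:
        raise ValueError(f"anchor-weighted GRAVY is defined for 9mers, got {len(peptide)}mer")
    anchors = set(anchors)
    if not anchors <= set(range(1, 10)):
        raise ValueError(f"anchor positions must be within 1..9, got {sorted(anchors)}")
    try:
        total = sum(scale[aa] for aa in peptide)
        anchor_total = sum(scale[peptide[pos - 1]] for pos in anchors)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from None
    return (total + anchor_total) / (9 + len(anchors))


def allele_mean_hydrophobicity(
    ligands_by_allele: Mapping[str, Iterable[str]],
    anchors_by_allele: Mapping[str, Iterable[int]] | None = None,
    scale: Mapping[str, float] = KYTE_DOOLITTLE,
) -> dict[str, float]:
    """Per-allele mean anchor-weighted GRAVY over that allele's 9mer ligands.

    Non-9mers are dropped (count logged); alleles left with no 9mers are
    omitted with a warning.  ``anchors_by_allele`` overrides the default
    P2/P-omega anchors per allele.
    """
    out: dict[str, float] = {}
    for allele, ligands in ligands_by_allele.items():
        anchors = (
            anchors_by_allele.get(allele, DEFAULT_ANCHORS)
            if anchors_by_allele
            else DEFAULT_ANCHORS
        )
        ligands = list(ligands)
        nine = [p for p in ligands if len(p) == 9]
        if len(nine) < len(ligands):
            logger.info(
                "%s: dropped %d non-9mer ligands", allele, len(ligands) - len(nine)
            )
        if not nine:
            logger.warning("%s: no 9mer ligands; omitted", allele)
            continue
        out[allele] = sum(anchor_weighted_gravy(p, anchors, scale) for p in nine) / len(nine)
    return out


def allele_fold_change(
    counts: Mapping[str, Mapping[str, int]],
    cond_a: str,
    cond_b: str,
    normalize: bool = True,
) -> dict[str, float]:
    """Fold change of per-allele ligand counts from condition a to b.

    In normalized mode each allele's count is first divided by the total
    ligand count of its condition, so the fold change compares the allele's
    *share* of the immunopeptidome: FC = (n_b/N_b) / (n_a/N_a).  Raw mode is
    n_b/n_a.  Alleles with a zero denominator are excluded with a warning,
    never a division error.
    """
    for cond in (cond_a, cond_b):
        if cond not in counts:
            raise ValueError(f"condition {cond!r} missing from counts table")
    a, b = counts[cond_a], counts[cond_b]
    totals = {c: sum(counts[c].values()) for c in (cond_a, cond_b)}
    out: dict[str, float] = {}
    for allele in sorted(set(a) | set(b)):
        n_a, n_b = a.get(allele, 0), b.get(allele, 0)
        if n_a == 0:
            logger.warning("%s: zero count in %s; excluded", allele, cond_a)
            continue
        if normalize:
            if totals[cond_a] == 0 or totals[cond_b] == 0:
                logger.warning("zero total in a condition; %s excluded", allele)
                continue
            out[allele] = (n_b / totals[cond_b]) / (n_a / totals[cond_a])
        else:
            out[allele] = n_b / n_a
    return out


def linear_regression(x: Iterable[float], y: Iterable[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the slope's two-sided t test.

    R^2 = 1 - SS_res/SS_tot; p-value from the slope's t statistic on n-2
    degrees of freedom.  Requires n >= 3 and non-constant x.
    """
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("regression requires at least 3 points")
    if len(set(x)) == 1:
        raise ValueError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
    )
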