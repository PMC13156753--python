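"""Synthetic immunopeptidomics data: motifs, ligands, planted proteomes.

Real eluted-ligand data cannot ship with the package, so every pipeline
stage is exercised on generated data with a known ground truth.  An
allele's presentation motif is a per-position probability table (PWM) over
the 20 residues, with anchor positions concentrating probability mass on
a small set of anchor residues — the generative definition of "presented
by this allele".  Ligands sampled from these motifs are planted into
random background proteins such that each ligand occurs at exactly one
place in the proteome, which makes the decoy pipeline's unique-source-
protein rule hold by construction.  A surrogate binding-affinity predictor
scores peptides by PWM log-likelihood, min-max scaled to s in [0,1] over a
reference sample of random peptides and mapped to pseudo-nM via
nM = 50000^(1-s), so the hard-negative (<=2000 nM) rule is exercisable
without any external tool.

The generator does not attempt biophysical realism: non-anchor positions
are uniform, background proteins are i.i.d. uniform residues, and there is
no model of MS detectability or elution chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CANONICAL_AA, Proteome

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
LENGTHS = (8, 9, 10, 11)

#: Class-I length bias: 9mers dominate.
DEFAULT_LENGTH_DISTRIBUTION = {8: 0.1, 9: 0.7, 10: 0.1, 11: 0.1}

NM_CEILING = 50000.0


def _anchor_positions_for_length(anchors_9mer: Sequence[int], length: int) -> list[int]:
    """Map 9mer anchor positions onto another length.

    The C-terminal anchor (position 9) maps to the last position; interior
    anchors keep their position when it fits before the C-terminus.
    """
    out = []
    for pos in anchors_9mer:
        if pos == 9:
            out.append(length)
        elif pos < length:
            out.append(pos)
    return sorted(set(out))


@dataclass
class MotifModel:
    """Per-allele presentation motif: one PWM per peptide length."""

    allele: str
    pwm: dict[int, np.ndarray]  # length -> (length, 20) row-stochastic
    anchor_positions: tuple[int, ...]  # 1-based, on the 9mer frame
    anchor_residues: Mapping[int, frozenset[str]]
    anchor_concentration: float

    def __post_init__(self):
        for length, table in self.pwm.items():
            if table.shape != (length, 20):
                raise ValueError(f"PWM for length {length} has shape {table.shape}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"PWM rows for length {length} do not sum to 1")


@dataclass
class SyntheticSample:
    """A multiallelic sample with ground truth."""

    sample_id: str
    alleles: list[str]
    positives: list[str]
    generating_allele: dict[str, str]
    proteome: Proteome
    seed: int


def make_motif(
    allele: str,
    anchor_positions: Sequence[int],
    anchor_residues: Mapping[int, Sequence[str]] | Sequence[str],
    anchor_concentration: float,
    seed: int = 0,
) -> MotifModel:
    """Build a motif whose anchors concentrate mass on given residues.

    At each anchor position, probability mass ``anchor_concentration`` is
    spread uniformly over that position's anchor residues and the remainder
    uniformly over the other residues; non-anchor positions are uniform.
    With concentration 1/20 and a single anchor residue this reduces
    exactly to the uniform PWM.  Deterministic given its arguments.
    """
    if not 0.0 < anchor_concentration <= 1.0:
        raise ValueError("anchor_concentration must be in (0, 1]")
    if not all(1 <= p <= 9 for p in anchor_positions):
        raise ValueError(f"anchor positions must be in 1..9, got {anchor_positions}")
    if not isinstance(anchor_residues, Mapping):
        anchor_residues = {p: anchor_residues for p in anchor_positions}
    residues_by_pos: dict[int, frozenset[str]] = {}
    for pos in anchor_positions:
        res = frozenset(anchor_residues[pos])
        if not res or not res <= set(CANONICAL_AA):
            raise ValueError(f"invalid anchor residues at position {pos}: {res}")
        residues_by_pos[pos] = res

    pwm: dict[int, np.ndarray] = {}
    for length in LENGTHS:
        table = np.full((length, 20), 1.0 / 20)
        for pos9 in anchor_positions:
            mapped = length if pos9 == 9 else (pos9 if pos9 < length else None)
            if mapped is None:
                continue
            res = residues_by_pos[pos9]
            row = np.full(20, (1.0 - anchor_concentration) / (20 - len(res)))
            for aa in res:
                row[AA_INDEX[aa]] = anchor_concentration / len(res)
            table[mapped - 1] = row
        pwm[length] = table
    return MotifModel(
        allele=allele,
        pwm=pwm,
        anchor_positions=tuple(sorted(anchor_positions)),
        anchor_residues=residues_by_pos,
        anchor_concentration=anchor_concentration,
    )


def sample_ligands(
    motif: MotifModel,
    n: int,
    length_distribution: Mapping[int, float] = None,
    seed: int = 0,
    unique: bool = False,
) -> list[str]:
    """Draw n ligands by independent positional sampling from the motif PWM.

    With ``unique=True`` duplicates are resampled so the result holds n
    distinct peptides.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = dict(length_distribution or DEFAULT_LENGTH_DISTRIBUTION)
    lengths = sorted(dist)
    probs = np.array([dist[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    aa = np.array(list(CANONICAL_AA))
    while len(out) < n:
        length = int(rng.choice(lengths, p=probs))
        table = motif.pwm[length]
        pep = "".join(
            aa[rng.choice(20, p=table[pos])] for pos in range(length)
        )
        if unique and pep in seen:
            continue
        seen.add(pep)
        out.append(pep)
    return out


def make_sample(
    motifs: Sequence[MotifModel],
    n_per_allele: int,
    proteome_shape: tuple[int, int],
    seed: int = 0,
    sample_id: str = "synthetic-1",
    length_distribution: Mapping[int, float] = None,
) -> SyntheticSample:
    """Generate a multiallelic sample with ligands planted into a toy proteome.

    Background proteins are i.i.d. uniform residues.  Each ligand is
    written over a non-occupied stretch of one protein; a placement that
    leaves the ligand occurring anywhere else in the proteome (e.g. a
    chance background match) is reverted and retried, so every positive
    maps uniquely to one source protein.
    """
    if len(motifs) > 6:
        raise ValueError("a sample carries at most six alleles")
    n_proteins, protein_len = proteome_shape
    rng = np.random.default_rng(seed)
    ligands: list[str] = []
    generating: dict[str, str] = {}
    for motif in motifs:
        drawn = sample_ligands(
            motif, n_per_allele, length_distribution,
            seed=int(rng.integers(2**31)), unique=True,
        )
        for pep in drawn:
            if pep not in generating:  # cross-allele duplicates: first wins
                generating[pep] = motif.allele
                ligands.append(pep)
    total_len = sum(len(p) for p in ligands)
    capacity = n_proteins * protein_len
    if total_len > capacity // 2:
        raise ValueError(
            f"proteome capacity {capacity} too small for {total_len} planted "
            f"residues; need at least {2 * total_len}"
        )

    aa = np.array(list(CANONICAL_AA))
    proteins = [
        list(rng.choice(aa, size=protein_len)) for _ in range(n_proteins)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_proteins)]

    def occurrences(pep: str) -> int:
        count = 0
        for chars in proteins:
            seq = "".join(chars)
            start = seq.find(pep)
            while start != -1:
                count += 1
                start = seq.find(pep, start + 1)
        return count

    for pep in ligands:
        placed = False
        for _ in range(200):
            pi = int(rng.integers(n_proteins))
            start = int(rng.integers(protein_len - len(pep) + 1))
            end = start + len(pep)
            if any(s < end and start < e for s, e in occupied[pi]):
                continue
            saved = proteins[pi][start:end]
            proteins[pi][start:end] = list(pep)
            if occurrences(pep) == 1:
                occupied[pi].append((start, end))
                placed = True
                break
            proteins[pi][start:end] = saved  # chance duplicate; retry elsewhere
        if not placed:
            raise RuntimeError(f"could not uniquely place ligand {pep}")

    entries = {f"SYN{idx:04d}": "".join(chars) for idx, chars in enumerate(proteins)}
    return SyntheticSample(
        sample_id=sample_id,
        alleles=[m.allele for m in motifs],
        positives=ligands,
        generating_allele=generating,
        proteome=Proteome(entries=entries),
        seed=seed,
    )


def make_pseudosequences(
    alleles: Sequence[str], length: int = 16, seed: int = 0
) -> dict[str, str]:
    """Synthetic fixed-length pseudosequences: random residue strings per allele."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(CANONICAL_AA))
    return {a: "".join(rng.choice(aa, size=length)) for a in alleles}


@dataclass
class SurrogateAffinity:
    """PWM-likelihood surrogate for a binding-affinity predictor.

    The log-likelihood of a peptide under the allele's motif is min-max
    scaled to s in [0,1] against a seeded reference sample of uniform
    random peptides and mapped to pseudo-nM by nM = 50000^(1-s) (the
    conventional affinity transform), so s=1 gives 1 nM and s=0 gives
    50,000 nM.  Deterministic for fixed inputs.
    """

    motifs: Mapping[str, MotifModel]
    n_reference: int = 2000
    reference_seed: int = 12345
    _log_pwm: dict = field(init=False, repr=False)
    _bounds: dict = field(init=False, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.reference_seed)
        self._log_pwm = {}
        self._bounds = {}
        for allele, motif in self.motifs.items():
            for length, table in motif.pwm.items():
                logp = np.log(table)
                self._log_pwm[(allele, length)] = logp
                ref = rng.integers(0, 20, size=(self.n_reference, length))
                ll = logp[np.arange(length), ref].sum(axis=1)
                lo, hi = float(ll.min()), float(ll.max())
                if hi <= lo:
                    hi = lo + 1e-9
                self._bounds[(allele, length)] = (lo, hi)

    def _loglik(self, encoded: np.ndarray, allele: str, length: int) -> np.ndarray:
        logp = self._log_pwm[(allele, length)]
        return logp[np.arange(length), encoded].sum(axis=-1)

    def predict(self, peptide: str, allele: str) -> float:
        return float(self.predict_many([peptide], allele)[0])

    def predict_many(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Vectorized affinities in nM, grouped internally by length."""
        if allele not in self.motifs:
            raise KeyError(f"no motif for allele {allele}")
        out = np.empty(len(peptides))
        by_length: dict[int, list[int]] = {}
        for i, pep in enumerate(peptides):
            by_length.setdefault(len(pep), []).append(i)
        for length, idx in by_length.items():
            if (allele, length) not in self._log_pwm:
                raise KeyError(f"no motif of length {length} for allele {allele}")
            enc = np.array(
                [[AA_INDEX[aa] for aa in peptides[i]] for i in idx], dtype=np.int64
            )
            ll = self._loglik(enc, allele, length)
            lo, hi = self._bounds[(allele, length)]
            s = np.clip((ll - lo) / (hi - lo), 0.0, 1.0)
            out[idx] = NM_CEILING ** (1.0 - s)
        return out


def surrogate_affinity(motifs: Sequence[MotifModel] | Mapping[str, MotifModel],
                       **kwargs) -> SurrogateAffinity:
    """Build a :class:`SurrogateAffinity` covering the given motifs."""
    if not isinstance(motifs, Mapping):
        motifs = {m.allele: m for m in motifs}
    return SurrogateAffinity(motifs=dict(motifs), **kwargs)
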