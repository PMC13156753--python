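"""Hard-negative decoy construction from the positives' source proteins.

Training a presentation classifier only on observed (eluted) ligands leaves
the negative class undefined.  The approach here builds synthetic negatives
from the non-presented 8-11mer fragments of the same proteins that yielded
the observed ligands — restricted to proteins the ligands map into
*uniquely* — then removes any candidate overlapping a known positive and
keeps only *hard* negatives: candidates a binding-affinity predictor still
scores as plausible binders (predicted BA at or below 2000 nM by default).
The surviving candidates are sampled without replacement at a configurable
negative:positive ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .io import MAX_LENGTH, MIN_LENGTH, Proteome

logger = logging.getLogger(__name__)

DEFAULT_BA_THRESHOLD_NM = 2000.0


class AffinityPredictor(Protocol):
    """Anything mapping a (peptide, allele) pair to a predicted affinity in nM.

    Lower is stronger binding.  Must be deterministic for fixed inputs.
    """

    def predict(self, peptide: str, allele: str) -> float: ...


@dataclass(frozen=True, order=True)
class CandidateFragment:
    """A candidate decoy: a fragment of a source protein.

    Ordering is (protein_id, start, length) — the canonical sort used to
    make downstream sampling independent of input file order.
    """

    protein_id: str
    start: int
    length: int
    sequence: str

    def __post_init__(self):
        if not (MIN_LENGTH <= self.length <= MAX_LENGTH):
            raise ValueError(f"fragment length {self.length} outside 8..11")
        if len(self.sequence) != self.length:
            raise ValueError("sequence/length mismatch")


@dataclass
class DecoySet:
    """Sampled hard-negative (fragment, allele) pairs."""

    pairs: list[tuple[CandidateFragment, str]]
    ratio_requested: int
    seed: int

    def sequences(self) -> set[str]:
        return {frag.sequence for frag, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class LigandMapping:
    """Result of mapping ligands onto a proteome."""

    unique: dict[str, str]          # peptide -> its single source protein
    multi_mapping: dict[str, list[str]]
    unmapped: list[str]
    positions: dict[str, list[tuple[str, int]]]  # peptide -> [(protein, start)]


def map_ligands_to_proteins(
    positives: Iterable[str], proteome: Proteome
) -> LigandMapping:
    """Map each ligand to its source protein, keeping unique matches only.

    A peptide is retained iff it occurs as a substring of exactly one
    protein (multiple occurrences within that one protein still count as
    unique).  Multi-mapping and unmapped peptides are reported separately.
    """
    if len(proteome) == 0:
        raise ValueError("empty proteome")
    unique: dict[str, str] = {}
    multi: dict[str, list[str]] = {}
    unmapped: list[str] = []
    positions: dict[str, list[tuple[str, int]]] = {}
    for peptide in dict.fromkeys(positives):  # preserve order, drop dups
        hits: list[str] = []
        for pid, seq in proteome.entries.items():
            start = seq.find(peptide)
            if start != -1:
                hits.append(pid)
                positions.setdefault(peptide, [])
                while start != -1:
                    positions[peptide].append((pid, start))
                    start = seq.find(peptide, start + 1)
        if len(hits) == 1:
            unique[peptide] = hits[0]
        elif len(hits) > 1:
            multi[peptide] = hits
            positions.pop(peptide, None)
        else:
            unmapped.append(peptide)
    logger.info(
        "ligand mapping: %d unique, %d multi-mapping, %d unmapped",
        len(unique), len(multi), len(unmapped),
    )
    return LigandMapping(unique=unique, multi_mapping=multi, unmapped=unmapped,
                         positions=positions)


def enumerate_candidates(
    protein_id: str,
    sequence: str,
    lengths: Sequence[int] = tuple(range(MIN_LENGTH, MAX_LENGTH + 1)),
) -> list[CandidateFragment]:
    """All 8-11mer substrings of a protein, left to right.

    The count is sum over k of max(0, L - k + 1).
    """
    out = []
    for k in lengths:
        for start in range(0, len(sequence) - k + 1):
            out.append(
                CandidateFragment(
                    protein_id=protein_id,
                    start=start,
                    length=k,
                    sequence=sequence[start : start + k],
                )
            )
    return out


def filter_overlaps(
    candidates: Iterable[CandidateFragment],
    positives: Iterable[str],
    mode: str = "sequence",
    positive_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[CandidateFragment]:
    """Remove candidates overlapping known positives.

    ``sequence`` mode (default) removes candidates whose sequence equals any
    positive sequence anywhere in the dataset.  ``interval`` mode
    additionally removes candidates whose [start, start+length) interval
    intersects a positive occurrence interval in the same protein;
    ``positive_intervals`` maps protein_id to half-open (start, end) pairs.
    """
    if mode not in ("sequence", "interval"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    positive_set = set(positives)
    kept = []
    removed = 0
    for cand in candidates:
        if cand.sequence in positive_set:
            removed += 1
            continue
        if mode == "interval":
            spans = (positive_intervals or {}).get(cand.protein_id, ())
            lo, hi = cand.start, cand.start + cand.length
            if any(lo < end and start < hi for start, end in spans):
                removed += 1
                continue
        kept.append(cand)
    logger.info("overlap filter (%s): removed %d, kept %d", mode, removed, len(kept))
    return kept


def filter_hard_negatives(
    candidates: Iterable[CandidateFragment],
    allele: str,
    predictor: AffinityPredictor,
    threshold_nm: float = DEFAULT_BA_THRESHOLD_NM,
    inclusive: bool = True,
) -> list[tuple[CandidateFragment, str]]:
    """Keep only candidates predicted to bind the allele at/below threshold.

    These are the *hard* negatives: non-presented peptides a pure
    binding-affinity model cannot tell apart from true ligands.  The
    boundary is inclusive by default (predicted == threshold kept).
    """
    candidates = list(candidates)
    try:
        if hasattr(predictor, "predict_many"):
            affinities = np.asarray(
                predictor.predict_many([c.sequence for c in candidates], allele)
            )
        else:
            affinities = np.array(
                [predictor.predict(c.sequence, allele) for c in candidates]
            )
    except Exception as exc:
        raise RuntimeError(
            f"affinity predictor failed for allele {allele}: {exc}"
        ) from exc
    passed = affinities <= threshold_nm if inclusive else affinities < threshold_nm
    return [(cand, allele) for cand, ok in zip(candidates, passed) if ok]


def sample_decoys(
    filtered_candidates: Sequence[tuple[CandidateFragment, str]],
    n_positives: int,
    ratio: int = 1000,
    seed: int = 0,
) -> DecoySet:
    """Sample decoys uniformly without replacement at ratio:1 to positives.

    Candidates are canonically sorted by (protein_id, start, length, allele)
    before sampling, so the drawn set depends only on the candidate *set*
    and the seed, not on input order.  If fewer than ratio * n_positives
    candidates survive the filters, all are returned and the shortfall is
    logged.
    """
    if n_positives < 1:
        raise ValueError("need at least one positive")
    pool = sorted(filtered_candidates, key=lambda t: (t[0], t[1]))
    want = ratio * n_positives
    rng = np.random.default_rng(seed)
    if want >= len(pool):
        if want > len(pool):
            logger.warning(
                "decoy shortfall: wanted %d, only %d candidates", want, len(pool)
            )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    return DecoySet(pairs=list(chosen), ratio_requested=ratio, seed=seed)


def generate_decoys(
    positives: Iterable[str],
    proteome: Proteome,
    alleles: Sequence[str],
    predictor: AffinityPredictor,
    ratio: int = 1000,
    threshold_nm: float = DEFAULT_BA_THRESHOLD_NM,
    overlap_mode: str = "sequence",
    seed: int = 0,
    inclusive: bool = True,
) -> DecoySet:
    """Full decoy pipeline: map, enumerate, overlap-filter, BA-filter, sample.

    Candidates are enumerated from the proteins the positives map into
    uniquely, and each candidate is paired with every allele whose affinity
    filter it passes.
    """
    positives = list(dict.fromkeys(positives))
    mapping = map_ligands_to_proteins(positives, proteome)
    source_proteins = sorted(set(mapping.unique.values()))
    candidates: list[CandidateFragment] = []
    for pid in source_proteins:
        candidates.extend(enumerate_candidates(pid, proteome[pid]))
    intervals: dict[str, list[tuple[int, int]]] = {}
    for pep, occs in mapping.positions.items():
        for pid, start in occs:
            intervals.setdefault(pid, []).append((start, start + len(pep)))
    candidates = filter_overlaps(
        candidates, positives, mode=overlap_mode, positive_intervals=intervals
    )
    pairs: list[tuple[CandidateFragment, str]] = []
    for allele in alleles:
        pairs.extend(
            filter_hard_negatives(
                candidates, allele, predictor, threshold_nm, inclusive
            )
        )
        logger.info("allele %s: %d hard-negative candidates", allele, len(pairs))
    return sample_decoys(pairs, n_positives=len(positives), ratio=ratio, seed=seed)
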