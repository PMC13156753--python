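"""Attention-MIL peptide-HLA presentation classifier.

A peptide observed in a multiallelic sample may have been presented by any
of the sample's (up to six) class-I alleles, so supervision exists only at
the *bag* level: the peptide was displayed by some allele.  Each candidate
(peptide, allele) instance is represented by the concatenation of the
peptide vector and the HLA pseudosequence vector produced by a shared
sequence encoder; a classifier MLP scores instances, and a tanh attention
module aggregates instance embeddings into a bag embedding

    a_i = softmax_i( w . tanh(V h_i) ),     bag = sum_i a_i h_i,

which the same MLP head maps through a sigmoid to the bag presentation
probability.  Sharing the head between instances and bags makes the
single-instance case an exact identity (bag probability == instance
probability) and lets monoallelic-style records — represented as
single-instance bags — supervise the instance scores directly.

Training minimizes binary cross-entropy on logits with label smoothing
(targets y(1-eps)+eps/2), AdamW with decoupled weight decay, gradient
accumulation, and early stopping on validation loss.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _autodiff as ad
from .decoys import AffinityPredictor
from .encoder import TransformerEncoder, tokenize_batch

logger = logging.getLogger(__name__)

MAX_ALLELES_PER_SAMPLE = 6


@dataclass
class Bag:
    """One peptide with its candidate alleles and (optionally) a label.

    A monoallelic-style record is simply a single-instance bag; a
    multiallelic observation carries up to six candidate alleles.
    """

    peptide: str
    alleles: list[str]
    label: int | None = None
    sample_id: str = ""

    def __post_init__(self):
        if not self.alleles:
            raise ValueError(f"bag for {self.peptide!r} has no candidate alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"bag for {self.peptide!r} has duplicate alleles")
        if len(self.alleles) > MAX_ALLELES_PER_SAMPLE:
            raise ValueError(
                f"bag for {self.peptide!r} has {len(self.alleles)} alleles; "
                f"at most {MAX_ALLELES_PER_SAMPLE} supported"
            )


@dataclass
class PredictionRecord:
    """Scored pHLA instance in the context of its bag."""

    peptide: str
    allele: str
    instance_probability: float
    bag_probability: float
    attention_weight: float
    filtered: bool = False


@dataclass
class ModelConfig:
    """Hyperparameters of the presentation classifier.

    Defaults follow the published training recipe: hidden sizes 128 for the
    classifier and MIL attention, label smoothing 0.1, learning rate 1e-4,
    weight decay 1e-4, batch size 512 with gradient accumulation 2, and
    early stopping with patience 10.  The encoder is a small from-scratch
    transformer (2 layers, dim 64, 4 heads).
    """

    encoder_layers: int = 2
    encoder_dim: int = 64
    encoder_heads: int = 4
    classifier_hidden: int = 128
    mil_hidden: int = 128
    gated_attention: bool = False
    label_smoothing: float = 0.1
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 512
    grad_accumulation: int = 2
    patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must be in [0, 0.5)")
        for name in ("encoder_layers", "encoder_dim", "encoder_heads",
                     "classifier_hidden", "mil_hidden", "batch_size",
                     "grad_accumulation", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def smooth_targets(y: np.ndarray, eps: float) -> np.ndarray:
    """Binary label smoothing: y' = y(1-eps) + eps/2."""
    return y * (1.0 - eps) + eps / 2.0


class EarlyStopping:
    """Stop when validation loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; True means stop now."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def fit_constant_probability(
    labels: Sequence[int],
    label_smoothing: float = 0.1,
    learning_rate: float = 0.1,
    n_steps: int = 2000,
) -> float:
    """Train a constant-capacity predictor (a single logit) on smoothed BCE.

    With label smoothing eps and an all-positive set the optimum is
    sigmoid(z) = 1 - eps/2; useful as a calibration check of the loss.
    """
    y = smooth_targets(np.asarray(labels, dtype=float), label_smoothing)
    z = ad.Tensor(np.zeros(1), requires_grad=True)
    opt = ad.AdamW({"z": z}, lr=learning_rate)
    ones = np.ones(len(y))
    for _ in range(n_steps):
        opt.zero_grad()
        logits = z * ad.Tensor(ones)
        loss = ad.bce_with_logits(logits, y)
        loss.backward()
        opt.step()
    return float(ad._sigmoid(z.data)[0])


class PresentationClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the encoder + attention-MIL head.

    ``fit`` consumes labelled :class:`Bag` objects (plus an allele ->
    pseudosequence table); ``predict_bags`` returns per-instance
    :class:`PredictionRecord` lists; ``predict_proba``/``predict`` expose
    the bag probabilities in the standard sklearn shape.
    """

    def __init__(self, encoder_layers: int = 2, encoder_dim: int = 64,
                 encoder_heads: int = 4, classifier_hidden: int = 128,
                 mil_hidden: int = 128, gated_attention: bool = False,
                 label_smoothing: float = 0.1, learning_rate: float = 1e-4,
                 weight_decay: float = 1e-4, batch_size: int = 512,
                 grad_accumulation: int = 2, patience: int = 10,
                 max_epochs: int = 100, seed: int = 0):
        self.encoder_layers = encoder_layers
        self.encoder_dim = encoder_dim
        self.encoder_heads = encoder_heads
        self.classifier_hidden = classifier_hidden
        self.mil_hidden = mil_hidden
        self.gated_attention = gated_attention
        self.label_smoothing = label_smoothing
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.grad_accumulation = grad_accumulation
        self.patience = patience
        self.max_epochs = max_epochs
        self.seed = seed

    # ------------------------------------------------------------------ setup

    @classmethod
    def from_config(cls, config: ModelConfig) -> "PresentationClassifier":
        return cls(**asdict(config))

    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.encoder_ = TransformerEncoder(
            n_layers=self.encoder_layers, dim=self.encoder_dim,
            n_heads=self.encoder_heads, seed=int(rng.integers(2**31)),
        )
        d2 = 2 * self.encoder_dim

        def init(n_in, n_out):
            return ad.Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)),
                requires_grad=True,
            )

        self.head_: dict[str, ad.Tensor] = {
            "cls_w1": init(d2, self.classifier_hidden),
            "cls_b1": ad.Tensor(np.zeros(self.classifier_hidden), requires_grad=True),
            "cls_w2": init(self.classifier_hidden, 1),
            "cls_b2": ad.Tensor(np.zeros(1), requires_grad=True),
            "att_v": init(d2, self.mil_hidden),
            "att_w": init(self.mil_hidden, 1),
        }
        if self.gated_attention:
            self.head_["att_u"] = init(d2, self.mil_hidden)
        self.params_ = dict(self.encoder_.params)
        self.params_.update({f"head.{k}": v for k, v in self.head_.items()})

    # ---------------------------------------------------------------- forward

    def _encode_sequences(self, sequences: list[str]) -> ad.Tensor:
        return self.encoder_.forward(tokenize_batch(sequences))

    def _hla_vectors(self, alleles: list[str]) -> ad.Tensor:
        missing = [a for a in alleles if a not in self.pseudosequences_]
        if missing:
            raise KeyError(
                f"alleles missing from pseudosequence table: {sorted(set(missing))}"
            )
        return self._encode_sequences([self.pseudosequences_[a] for a in alleles])

    def _forward_bags(self, bags: Sequence[Bag]):
        """Instance logits, attention weights and bag logits for a batch.

        Returns (instance_logits (B,K), attention (B,K), bag_logits (B,),
        instance_mask (B,K)) with K the batch-max bag size.
        """
        n = len(bags)
        k_max = max(len(b.alleles) for b in bags)
        pep_vecs = self._encode_sequences([b.peptide for b in bags])  # (B, D)
        unique_alleles = sorted({a for b in bags for a in b.alleles})
        allele_vecs = self._hla_vectors(unique_alleles)  # (U, D)
        allele_index = {a: i for i, a in enumerate(unique_alleles)}

        gather = np.zeros((n, k_max), dtype=np.int64)
        mask = np.zeros((n, k_max), dtype=np.float64)
        for i, bag in enumerate(bags):
            for j, allele in enumerate(bag.alleles):
                gather[i, j] = allele_index[allele]
                mask[i, j] = 1.0

        hla = allele_vecs[gather.reshape(-1)].reshape(n, k_max, self.encoder_dim)
        pep = pep_vecs.reshape(n, 1, self.encoder_dim) * ad.Tensor(
            np.ones((1, k_max, 1))
        )
        # instance embedding: concat(peptide vector, HLA vector)
        d = self.encoder_dim
        h_data = np.concatenate([pep.data, hla.data], axis=-1)
        h = ad.Tensor(h_data)
        h.requires_grad = pep.requires_grad or hla.requires_grad
        if h.requires_grad:
            h._parents = (pep, hla)

            def backward(g, pep=pep, hla=hla, d=d):
                if pep.requires_grad:
                    pep._accum(g[..., :d])
                if hla.requires_grad:
                    hla._accum(g[..., d:])

            h._backward = backward

        hd = self.head_
        hidden = (ad.linear(h, hd["cls_w1"], hd["cls_b1"])).relu()
        inst_logits = ad.linear(hidden, hd["cls_w2"], hd["cls_b2"])[..., 0]  # (B,K)

        att_pre = ad.linear(h, hd["att_v"]).tanh()
        if self.gated_attention:
            att_pre = att_pre * ad.linear(h, hd["att_u"]).sigmoid()
        att_scores = ad.linear(att_pre, hd["att_w"])[..., 0]  # (B, K)
        att_scores = att_scores + ad.Tensor((1.0 - mask) * -1e9)
        attention = att_scores.softmax(axis=-1)

        bag_emb = (attention.reshape(n, k_max, 1) * h).sum(axis=1)  # (B, 2D)
        bag_hidden = ad.linear(bag_emb, hd["cls_w1"], hd["cls_b1"]).relu()
        bag_logits = ad.linear(bag_hidden, hd["cls_w2"], hd["cls_b2"])[..., 0]
        return inst_logits, attention, bag_logits, mask

    # -------------------------------------------------------------------- fit

    def fit(self, X: Sequence[Bag], y=None, *, pseudosequences: Mapping[str, str],
            val_bags: Sequence[Bag] | None = None, val_fraction: float = 0.15):
        """Train on labelled bags.

        ``pseudosequences`` maps every allele in use to its binding-groove
        pseudosequence.  If ``val_bags`` is not given, a peptide-level split
        holds out ``val_fraction`` of the bags.  Training and validation
        peptide sets must be disjoint.
        """
        bags = list(X)
        if y is not None:
            bags = [
                Bag(b.peptide, b.alleles, int(label), b.sample_id)
                for b, label in zip(bags, y)
            ]
        if any(b.label is None for b in bags):
            raise ValueError("all training bags need labels")
        lengths = {len(p) for p in set(pseudosequences.values())}
        if len(lengths) > 1:
            raise ValueError(f"pseudosequences have mixed lengths {sorted(lengths)}")
        self.pseudosequences_ = dict(pseudosequences)

        rng = np.random.default_rng(self.seed)
        if val_bags is None:
            peptides = sorted({b.peptide for b in bags})
            perm = rng.permutation(len(peptides))
            n_val = max(1, int(round(val_fraction * len(peptides))))
            val_set = {peptides[i] for i in perm[:n_val]}
            val_bags = [b for b in bags if b.peptide in val_set]
            train_bags = [b for b in bags if b.peptide not in val_set]
        else:
            train_bags = bags
            val_bags = list(val_bags)
        if not train_bags or not val_bags:
            raise ValueError("both training and validation splits must be nonempty")
        leaked = {b.peptide for b in train_bags} & {b.peptide for b in val_bags}
        if leaked:
            raise ValueError(
                f"peptides appear in both splits: {sorted(leaked)[:10]}"
                + ("..." if len(leaked) > 10 else "")
            )

        self._build()
        opt = ad.AdamW(self.params_, lr=self.learning_rate,
                       weight_decay=self.weight_decay)
        stopper = EarlyStopping(self.patience)
        self.history_: list[dict[str, float]] = []
        best_weights = None

        order = np.arange(len(train_bags))
        for epoch in range(1, self.max_epochs + 1):
            rng.shuffle(order)
            epoch_losses = []
            opt.zero_grad()
            since_step = 0
            for start in range(0, len(order), self.batch_size):
                batch = [train_bags[i] for i in order[start : start + self.batch_size]]
                _, _, bag_logits, _ = self._forward_bags(batch)
                targets = smooth_targets(
                    np.array([b.label for b in batch], dtype=float),
                    self.label_smoothing,
                )
                loss = ad.bce_with_logits(bag_logits, targets)
                (loss * (1.0 / self.grad_accumulation)).backward()
                epoch_losses.append(float(loss.data) * len(batch))
                since_step += 1
                if since_step == self.grad_accumulation:
                    opt.step()
                    opt.zero_grad()
                    since_step = 0
            if since_step:
                opt.step()
                opt.zero_grad()
            train_loss = float(np.sum(epoch_losses) / len(train_bags))
            val_loss = self._eval_loss(val_bags)
            self.history_.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
            if val_loss < stopper.best:
                best_weights = {k: p.data.copy() for k, p in self.params_.items()}
            if stopper.update(epoch, val_loss):
                logger.info("early stop at epoch %d (best %d)", epoch, stopper.best_epoch)
                break
        if best_weights is not None:
            for k, p in self.params_.items():
                p.data = best_weights[k]
        self.best_epoch_ = stopper.best_epoch
        self.n_epochs_ = len(self.history_)
        self.classes_ = np.array([0, 1])
        return self

    def _eval_loss(self, bags: Sequence[Bag]) -> float:
        total = 0.0
        for start in range(0, len(bags), self.batch_size):
            batch = bags[start : start + self.batch_size]
            _, _, bag_logits, _ = self._forward_bags(batch)
            targets = smooth_targets(
                np.array([b.label for b in batch], dtype=float),
                self.label_smoothing,
            )
            total += float(ad.bce_with_logits(bag_logits, targets).data) * len(batch)
        return total / len(bags)

    # ------------------------------------------------------------ persistence

    def save(self, model_dir) -> None:
        """Write weights, hyperparameters and the pseudosequence snapshot."""
        from pathlib import Path
        import yaml

        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "weights.npz",
                 **{k: p.data for k, p in self.params_.items()})
        (model_dir / "config.yaml").write_text(
            yaml.safe_dump(self.get_params(), sort_keys=True)
        )
        from .io import write_pseudosequences

        write_pseudosequences(self.pseudosequences_, model_dir / "pseudosequences.tsv")

    @classmethod
    def load(cls, model_dir) -> "PresentationClassifier":
        from pathlib import Path
        import yaml

        from .io import read_pseudosequences

        model_dir = Path(model_dir)
        params = yaml.safe_load((model_dir / "config.yaml").read_text())
        est = cls(**params)
        est.pseudosequences_ = read_pseudosequences(model_dir / "pseudosequences.tsv")
        est._build()
        with np.load(model_dir / "weights.npz") as weights:
            for key, tensor in est.params_.items():
                tensor.data = weights[key].astype(tensor.data.dtype)
        est.classes_ = np.array([0, 1])
        return est

    # ---------------------------------------------------------------- predict

    def score_bag(self, bag: Bag) -> list[PredictionRecord]:
        """Score one bag; attention weights over its instances sum to 1."""
        return self.predict_bags([bag])[0]

    def predict_bags(self, bags: Sequence[Bag]) -> list[list[PredictionRecord]]:
        """Per-instance records for each bag (no affinity pre-filter)."""
        out: list[list[PredictionRecord]] = []
        for start in range(0, len(bags), self.batch_size):
            batch = list(bags[start : start + self.batch_size])
            inst_logits, attention, bag_logits, mask = self._forward_bags(batch)
            inst_p = ad._sigmoid(inst_logits.data)
            bag_p = ad._sigmoid(bag_logits.data)
            for i, bag in enumerate(batch):
                records = [
                    PredictionRecord(
                        peptide=bag.peptide,
                        allele=allele,
                        instance_probability=float(inst_p[i, j]),
                        bag_probability=float(bag_p[i]),
                        attention_weight=float(attention.data[i, j]),
                    )
                    for j, allele in enumerate(bag.alleles)
                ]
                out.append(records)
        return out

    def predict_proba(self, X: Sequence[Bag]) -> np.ndarray:
        """Bag presentation probabilities, sklearn-style (n, 2)."""
        p = np.array([recs[0].bag_probability for recs in self.predict_bags(X)])
        return np.column_stack([1.0 - p, p])

    def predict(self, X: Sequence[Bag]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_presentation(
        self,
        peptides: Sequence[str],
        alleles: Sequence[str],
        ba_filter: AffinityPredictor | None = None,
        ba_threshold_nm: float = 2000.0,
    ) -> list[PredictionRecord]:
        """Score every peptide x allele pair of a multiallelic sample.

        With ``ba_filter`` set, instances whose predicted binding affinity
        exceeds the threshold are excluded from the bag before attention is
        applied, and reported with ``filtered=True`` and NaN instance
        probability.  A bag whose instances are all filtered is reported as
        not presented (bag probability 0).
        """
        alleles = list(dict.fromkeys(alleles))
        records: list[PredictionRecord] = []
        kept_bags: list[Bag] = []
        filtered_by_peptide: dict[str, list[str]] = {}
        for peptide in peptides:
            keep, dropped = [], []
            for allele in alleles:
                if ba_filter is not None and ba_filter.predict(peptide, allele) > ba_threshold_nm:
                    dropped.append(allele)
                else:
                    keep.append(allele)
            filtered_by_peptide[peptide] = dropped
            if keep:
                kept_bags.append(Bag(peptide=peptide, alleles=keep))
            else:
                logger.warning(
                    "all alleles filtered for %s; reported not presented", peptide
                )
        scored = {b.peptide: recs for b, recs in zip(kept_bags, self.predict_bags(kept_bags))}
        for peptide in peptides:
            recs = scored.get(peptide, [])
            records.extend(recs)
            bag_p = recs[0].bag_probability if recs else 0.0
            for allele in filtered_by_peptide[peptide]:
                records.append(
                    PredictionRecord(
                        peptide=peptide, allele=allele,
                        instance_probability=float("nan"),
                        bag_probability=bag_p, attention_weight=0.0,
                        filtered=True,
                    )
                )
        return records
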