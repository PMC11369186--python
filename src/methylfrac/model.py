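"""Joint sequence + methylation read encoding and the per-read classifier.

A read is encoded as an L x 5 matrix: four one-hot DNA channels (A, C, G,
T; N and right-padding are all-zero) and a methylation channel that is +1
at the C of a methylated CpG, -1 at the C of an unmethylated CpG, and 0
elsewhere.  The classifier maps this encoding to the probability that the
read is tumor-derived.

The network is a compact 1-D convolutional architecture implemented
directly in numpy with analytic gradients and Adam updates: a convolution
over the 5-channel encoding extracts local sequence/methylation features,
ReLU + max-pooling condenses them, and position-aware dense layers
aggregate the feature map into a sigmoid read score.  Training is
deterministic for a fixed seed (pure numpy, single process): the seed
fixes initialization, the train/validation split, epoch shuffling and
class-balance downsampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import ConfigError, DataError, MethylRead, Region, assign_reads_to_regions
from .regions import compute_alpha

__all__ = [
    "ModelSpec",
    "ReadClassifier",
    "TrainingSet",
    "ReadScoringResult",
    "encode_read",
    "encode_reads",
    "decode_sequence",
    "build_training_set",
    "train_read_classifier",
    "score_reads",
    "region_set_checksum",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_read(read: MethylRead, L: int = 66) -> np.ndarray:
    """Encode one read as an (L, 5) float32 matrix.

    Reads longer than L are trimmed from the 3' end; shorter reads are
    zero-padded on the right.  CpG offsets falling outside the window are
    dropped (the CpG of an offset at L-1 would lose its G and is dropped
    too, keeping the methylation channel consistent with the visible
    sequence).
    """
    if L < 1:
        raise ConfigError(f"window length L must be >= 1, got {L}")
    out = np.zeros((L, 5), dtype=np.float32)
    seq = read.sequence[:L]
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is not None:
            out[i, j] = 1.0
    for off, state in zip(read.cpg_offsets, read.cpg_states):
        if off + 1 < L:
            out[off, 4] = 1.0 if state else -1.0
    return out


def encode_reads(reads: Sequence[MethylRead], L: int = 66) -> np.ndarray:
    """Stack encodings into an (n, L, 5) array."""
    if not reads:
        return np.zeros((0, L, 5), dtype=np.float32)
    return np.stack([encode_read(r, L) for r in reads])


def decode_sequence(encoded: np.ndarray) -> str:
    """Invert the sequence channels over non-padded positions."""
    out = []
    for row in encoded:
        onehot = row[:4]
        if onehot.sum() == 0:
            if np.any(row != 0):
                out.append("N")  # an N with a methylation mark cannot occur
            else:
                break  # padding (or an N tail; both decode to the trimmed read)
        else:
            out.append(_INDEX_BASE[int(np.argmax(onehot))])
    return "".join(out)


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Hyperparameters of the read classifier.

    The defaults are sized for desk-scale training sets (thousands of
    reads): a 66 bp window, 32 convolution filters of width 8, pool size 2,
    a 16-unit hidden layer, Adam at 1e-3, batch 64, 12 epochs.
    """

    window_length: int = 66
    conv_filters: int = 32
    conv_width: int = 8
    pool_size: int = 2
    hidden_units: int = 16
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 12
    val_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> "ModelSpec":
        for name in (
            "window_length",
            "conv_filters",
            "conv_width",
            "pool_size",
            "hidden_units",
            "batch_size",
            "epochs",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.conv_width > self.window_length:
            raise ConfigError("conv_width must not exceed window_length")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0,1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError("val_fraction must be in (0,1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        return self

    @property
    def conv_out_len(self) -> int:
        return self.window_length - self.conv_width + 1

    @property
    def pooled_len(self) -> int:
        return self.conv_out_len // self.pool_size

    @property
    def flat_dim(self) -> int:
        return self.pooled_len * self.conv_filters


def region_set_checksum(regions: Sequence[Region]) -> str:
    """Stable checksum of a region set, stored with the model artifact."""
    h = hashlib.sha256()
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.id)):
        h.update(f"{r.chrom}:{r.start}-{r.end}:{r.id}:{r.direction}".encode())
    return h.hexdigest()[:16]


class ReadClassifier:
    """Numpy 1-D conv network scoring reads for tumor origin.

    Layers: conv(conv_filters x conv_width over 5 channels) -> ReLU ->
    max-pool(pool_size) -> flatten -> dense(hidden_units, ReLU) ->
    dense(1) -> sigmoid.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        spec.validate()
        self.spec = spec
        self.region_checksum: str | None = None
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        w, f, h = spec.conv_width, spec.conv_filters, spec.hidden_units
        d = spec.flat_dim
        # He initialization for the ReLU layers, Glorot for the output
        self.params = {
            "Wc": rng.normal(0.0, np.sqrt(2.0 / (w * 5)), size=(w * 5, f)),
            "bc": np.zeros(f),
            "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0.0, np.sqrt(1.0 / h), size=(h, 1)),
            "b2": np.zeros(1),
        }

    # -- forward -----------------------------------------------------------
    def _im2col(self, X: np.ndarray) -> np.ndarray:
        w = self.spec.conv_width
        cols = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
        # (B, T, 5, w) -> (B, T, w, 5) -> (B, T, w*5)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        return cols.reshape(cols.shape[0], cols.shape[1], w * 5)

    def _forward(self, X: np.ndarray):
        s = self.spec
        cols = self._im2col(np.asarray(X, dtype=np.float64))
        z1 = cols @ self.params["Wc"] + self.params["bc"]  # (B,T,F)
        a1 = np.maximum(z1, 0.0)
        t2 = s.pooled_len
        windows = a1[:, : t2 * s.pool_size].reshape(
            a1.shape[0], t2, s.pool_size, s.conv_filters
        )
        arg = np.argmax(windows, axis=2)
        pooled = np.max(windows, axis=2)  # (B,T2,F)
        flat = pooled.reshape(pooled.shape[0], -1)
        h = np.maximum(flat @ self.params["W1"] + self.params["b1"], 0.0)
        logits = (h @ self.params["W2"] + self.params["b2"]).ravel()
        prob = 1.0 / (1.0 + np.exp(-logits))
        cache = (cols, z1, arg, flat, h, prob)
        return prob, cache

    def predict_proba(self, X: np.ndarray, chunk: int = 8192) -> np.ndarray:
        """Per-read tumor probability; deterministic given the artifact."""
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        out = np.empty(X.shape[0])
        for i in range(0, X.shape[0], chunk):
            out[i : i + chunk] = self._forward(X[i : i + chunk])[0]
        return out

    # -- loss and gradients ------------------------------------------------
    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray, dropout_rng=None):
        s = self.spec
        prob, (cols, z1, arg, flat, h, _) = self._forward(X)
        if dropout_rng is not None and s.dropout > 0.0:
            keep = (dropout_rng.random(flat.shape) >= s.dropout) / (1.0 - s.dropout)
            flat = flat * keep
            h = np.maximum(flat @ self.params["W1"] + self.params["b1"], 0.0)
            logits = (h @ self.params["W2"] + self.params["b2"]).ravel()
            prob = 1.0 / (1.0 + np.exp(-logits))
        B = X.shape[0]
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        # output layer
        dz2 = ((prob - y) / B)[:, None]  # (B,1)
        grads = {
            "W2": h.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dh = (dz2 @ self.params["W2"].T) * (h > 0)
        grads["W1"] = flat.T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ self.params["W1"].T
        if dropout_rng is not None and s.dropout > 0.0:
            dflat = dflat * keep
        dpool = dflat.reshape(B, s.pooled_len, s.conv_filters)
        # un-pool: route gradient to the argmax position in each window
        da1 = np.zeros((B, s.pooled_len, s.pool_size, s.conv_filters))
        np.put_along_axis(da1, arg[:, :, None, :], dpool[:, :, None, :], axis=2)
        da1_full = np.zeros((B, s.conv_out_len, s.conv_filters))
        da1_full[:, : s.pooled_len * s.pool_size] = da1.reshape(
            B, s.pooled_len * s.pool_size, s.conv_filters
        )
        dz1 = da1_full * (z1 > 0)
        grads["Wc"] = cols.reshape(-1, cols.shape[-1]).T @ dz1.reshape(
            -1, s.conv_filters
        )
        grads["bc"] = dz1.sum(axis=(0, 1))
        return loss, grads

    # -- persistence -------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        """Write the model artifact: weights, spec JSON, region checksum."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "weights.npz", **self.params)
        meta = {"spec": asdict(self.spec), "region_checksum": self.region_checksum}
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "ReadClassifier":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        model = cls(ModelSpec(**meta["spec"]))
        model.region_checksum = meta["region_checksum"]
        with np.load(outdir / "weights.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        return model


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Encoded, labeled, class-balanced reads ready for training."""

    X: np.ndarray  # (n, L, 5)
    y: np.ndarray  # (n,) 1 = tumor-pattern positive
    n_positive_raw: int = 0
    n_negative_raw: int = 0
    region_checksum: str = ""


def build_training_set(
    reads_by_region: dict[str, list[MethylRead]],
    selected_regions: Sequence[Region],
    manifest: pd.DataFrame,
    positive_group: str = "tumor_tissue",
    negative_groups: Sequence[str] = ("normal_tissue", "noncancer_urine"),
    label_col: str = "group",
    alpha_lo: float = 0.2,
    alpha_hi: float = 0.8,
    min_cpgs: int = 3,
    L: int = 66,
    seed: int = 0,
    balance: bool = True,
) -> TrainingSet:
    """Label and encode reads from the selected regions.

    Positives are reads from ``positive_group`` samples whose alpha lies on
    the region's aberrant side (hypo regions: alpha <= alpha_lo; hyper:
    alpha >= alpha_hi) — in tumor tissue only the aberrant read
    subpopulation carries the tumor pattern.  Negatives are all
    alpha-qualifying reads from ``negative_groups`` in the same regions,
    unfiltered.  The majority class is downsampled to the minority size
    under ``seed``.
    """
    groups = dict(zip(manifest["sample_id"], manifest[label_col]))
    neg = set(negative_groups)
    directions = {r.id: r.direction for r in selected_regions}
    if any(d not in ("hypo", "hyper") for d in directions.values()):
        raise ConfigError("every selected region needs direction hypo/hyper")
    pos_reads: list[MethylRead] = []
    neg_reads: list[MethylRead] = []
    for region in selected_regions:
        for read in reads_by_region.get(region.id, []):
            ra = compute_alpha(read, min_cpgs)
            if ra is None:
                continue
            g = groups.get(read.sample_id)
            if g == positive_group:
                aberrant = (
                    ra.alpha <= alpha_lo
                    if directions[region.id] == "hypo"
                    else ra.alpha >= alpha_hi
                )
                if aberrant:
                    pos_reads.append(read)
            elif g in neg:
                neg_reads.append(read)
    if not pos_reads or not neg_reads:
        raise ConfigError(
            f"empty training class (positives={len(pos_reads)}, "
            f"negatives={len(neg_reads)})"
        )
    n_pos_raw, n_neg_raw = len(pos_reads), len(neg_reads)
    if balance:
        rng = np.random.default_rng(seed)
        m = min(n_pos_raw, n_neg_raw)
        if n_pos_raw > m:
            pos_reads = [pos_reads[i] for i in rng.choice(n_pos_raw, m, replace=False)]
        if n_neg_raw > m:
            neg_reads = [neg_reads[i] for i in rng.choice(n_neg_raw, m, replace=False)]
    X = np.concatenate([encode_reads(pos_reads, L), encode_reads(neg_reads, L)])
    y = np.concatenate(
        [np.ones(len(pos_reads)), np.zeros(len(neg_reads))]
    )
    return TrainingSet(
        X=X,
        y=y,
        n_positive_raw=n_pos_raw,
        n_negative_raw=n_neg_raw,
        region_checksum=region_set_checksum(selected_regions),
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_read_classifier(
    train_set: TrainingSet, spec: ModelSpec
) -> tuple[ReadClassifier, pd.DataFrame]:
    """Train the classifier with Adam on binary cross-entropy.

    A read-level held-out split (``spec.val_fraction``) tracks validation
    loss and AUC per epoch.  Returns the trained model and the training log
    (epoch, train_loss, val_loss, val_auc).  Raises on non-finite loss.
    """
    spec.validate()
    X, y = train_set.X, train_set.y
    if X.shape[0] < 4 or len(np.unique(y)) < 2:
        raise ConfigError("training set needs >= 4 reads and both classes")
    rng = np.random.default_rng(spec.seed)
    model = ReadClassifier(spec, rng)
    model.region_checksum = train_set.region_checksum or None

    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(spec.val_fraction * X.shape[0])))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
        # tiny sets: fall back to a stratified split
        pos = np.flatnonzero(y == 1)
        negi = np.flatnonzero(y == 0)
        rng.shuffle(pos), rng.shuffle(negi)
        kp = max(1, int(round(spec.val_fraction * pos.size)))
        kn = max(1, int(round(spec.val_fraction * negi.size)))
        val_idx = np.concatenate([pos[:kp], negi[:kn]])
        tr_idx = np.concatenate([pos[kp:], negi[kn:]])
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    log = []
    for epoch in range(spec.epochs):
        order = rng.permutation(Xtr.shape[0])
        batch_losses = []
        for i in range(0, order.size, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            loss, grads = model._loss_and_grads(
                Xtr[idx], ytr[idx], dropout_rng=rng if spec.dropout > 0 else None
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step} "
                    f"(lr={spec.learning_rate}); inspect input scaling"
                )
            batch_losses.append(loss)
            step += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                model.params[k] = model.params[k] - spec.learning_rate * mhat / (
                    np.sqrt(vhat) + eps
                )
        val_prob = model.predict_proba(Xval)
        val_loss = float(
            -np.mean(
                yval * np.log(val_prob + 1e-12)
                + (1 - yval) * np.log(1 - val_prob + 1e-12)
            )
        )
        val_auc = float(roc_auc_score(yval, val_prob))
        log.append(
            dict(
                epoch=epoch,
                train_loss=float(np.mean(batch_losses)),
                val_loss=val_loss,
                val_auc=val_auc,
            )
        )
    return model, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class ReadScoringResult:
    """Per-read tumor probabilities plus an explicit account of skips."""

    scores: np.ndarray
    reads: list[MethylRead]
    n_skipped_outside_regions: int
    n_skipped_few_cpgs: int
    reason: str | None = None  # set when scores is empty

    @property
    def n_scored(self) -> int:
        return int(self.scores.size)


def score_reads(
    model: ReadClassifier,
    reads: Sequence[MethylRead],
    selected_regions: Sequence[Region],
    min_cpgs: int = 3,
) -> ReadScoringResult:
    """Score every qualifying read of a sample.

    Qualifying means: at least one CpG inside a selected region, and at
    least ``min_cpgs`` CpGs on the read.  Non-qualifying reads are counted,
    never silently dropped.  An empty result carries a reason string.
    """
    expected = region_set_checksum(selected_regions)
    if model.region_checksum is not None and model.region_checksum != expected:
        raise DataError(
            "model was trained on a different region set "
            f"(artifact {model.region_checksum}, given {expected})"
        )
    by_region = assign_reads_to_regions(reads, selected_regions)
    seen: set[int] = set()
    kept: list[MethylRead] = []
    n_few = 0
    for region_reads in by_region.values():
        for read in region_reads:
            if id(read) in seen:
                continue  # a read spanning two regions is scored once
            seen.add(id(read))
            if len(read.cpg_offsets) < min_cpgs:
                n_few += 1
                continue
            kept.append(read)
    n_outside = len(reads) - len(seen)
    if not kept:
        return ReadScoringResult(
            scores=np.empty(0),
            reads=[],
            n_skipped_outside_regions=n_outside,
            n_skipped_few_cpgs=n_few,
            reason="no_informative_reads",
        )
    X = encode_reads(kept, model.spec.window_length)
    return ReadScoringResult(
        scores=model.predict_proba(X),
        reads=kept,
        n_skipped_outside_regions=n_outside,
        n_skipped_few_cpgs=n_few,
    )
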