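"""End-to-end training of the dual-branch model and the evaluation metrics.

Training follows a two-stage protocol: each branch (cell-graph GCN,
semantic CNN) is first trained on its own with a linear classifier head
(Adam, lr 0.001); the fused model then fine-tunes the pretrained
encoders at a much smaller learning rate (1e-5) while the freshly
initialized gated Kronecker fusion head trains at the branch rate.
Defaults are desk scale (64 px CNN input, vgg_small, 30 epochs,
batch 16) and run on one CPU; the full-scale settings (batch 64,
100 fine-tune epochs, vgg16) are plain config values.

Metrics are per-class one-vs-rest precision / recall / F1 percentages
plus overall (micro) accuracy, mirroring the standard confusion-table
definitions P = TP/(TP+FP), R = TP/(TP+FN), F1S = 2TP/(2TP+FP+FN),
accuracy = (TP+TN)/total.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from . import autodiff as ad
from .cell_features import FeatureNormalizer, featurize_tile
from .cell_graph import DEFAULT_D, DEFAULT_K, build_graph
from .cnn_encoder import CNNConfig, CNNEncoder
from .fusion_head import FusionConfig, FusionHead
from .gcn_encoder import GCNConfig, GCNEncoder

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "Sample",
    "make_sample",
    "load_samples",
    "stratified_split",
    "TrainedModel",
    "TrainResult",
    "init_model",
    "train",
    "train_from_manifest",
    "evaluate",
    "compute_metrics",
]

MODES = ("gcn_only", "cnn_only", "fused")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    mode: str = "fused"
    lr: float = 0.001
    finetune_lr: float = 0.00001
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclasses.dataclass
class MetricsReport:
    """Per-class one-vs-rest counts and percentages plus micro accuracy."""

    confusion: np.ndarray  # confusion[true, pred]
    per_class: pd.DataFrame  # TP FP FN TN P R F1S per class
    accuracy: float  # percent

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.per_class}\naccuracy: {self.accuracy:.2f}%"


def compute_metrics(y_true, y_pred, n_classes: int, class_names: Sequence[str] | None = None) -> MetricsReport:
    """Confusion-table metrics; P/R are 0 (with a warning) on empty denominators."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    total = confusion.sum()
    rows = []
    for c in range(n_classes):
        tp = int(confusion[c, c])
        fp = int(confusion[:, c].sum() - tp)
        fn = int(confusion[c, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        if tp + fp == 0:
            warnings.warn(f"class {c}: no predicted positives; precision set to 0")
            p = 0.0
        else:
            p = 100.0 * tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"class {c}: no true positives in data; recall set to 0")
            r = 0.0
        else:
            r = 100.0 * tp / (tp + fn)
        f1 = 0.0 if (2 * tp + fp + fn) == 0 else 100.0 * 2 * tp / (2 * tp + fp + fn)
        rows.append({"TP": tp, "FP": fp, "FN": fn, "TN": tn, "P": p, "R": r, "F1S": f1})
    index = list(class_names) if class_names is not None else list(range(n_classes))
    per_class = pd.DataFrame(rows, index=index)
    accuracy = 100.0 * np.trace(confusion) / total
    return MetricsReport(confusion=confusion, per_class=per_class, accuracy=float(accuracy))


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Sample:
    """One tile prepared for the model: CNN image tensor + cell graph."""

    image_small: np.ndarray  # (3, s, s) float in [0, 1]
    feats: np.ndarray  # (m, f) raw node features
    a_norm: np.ndarray  # (m, m)
    name: str = ""


def make_sample(
    image: np.ndarray,
    instance_mask: np.ndarray,
    k: int = DEFAULT_K,
    d: float = DEFAULT_D,
    image_size: int = 64,
    descriptor: Callable | None = None,
    name: str = "",
) -> Sample:
    feats, centroids = featurize_tile(image, instance_mask, descriptor=descriptor)
    graph = build_graph(centroids, feats, k=k, d=d) if feats.shape[0] else None
    a_norm = graph.a_norm if graph is not None else np.zeros((0, 0))
    small = resize(np.asarray(image, dtype=np.float64) / 255.0, (image_size, image_size, 3), anti_aliasing=True)
    return Sample(image_small=small.transpose(2, 0, 1), feats=feats, a_norm=a_norm, name=name)


def load_samples(
    manifest: pd.DataFrame,
    root: str | Path,
    k: int = DEFAULT_K,
    d: float = DEFAULT_D,
    image_size: int = 64,
    descriptor: Callable | None = None,
) -> tuple[list[Sample], np.ndarray, tuple[str, ...]]:
    """Read manifest tiles/masks and prepare samples; labels are indices
    into the (sorted) class-name tuple."""
    root = Path(root)
    class_names = tuple(sorted(manifest["label"].unique()))
    samples, labels = [], []
    for _, row in manifest.iterrows():
        image = iio.imread(root / row["tile"])
        mask = iio.imread(root / row["mask"]).astype(np.int32)
        samples.append(make_sample(image, mask, k=k, d=d, image_size=image_size, descriptor=descriptor, name=str(row["tile"])))
        labels.append(class_names.index(row["label"]))
    return samples, np.asarray(labels, dtype=np.int64), class_names


def stratified_split(labels: np.ndarray, fractions: tuple[float, float, float], seed: int):
    """Deterministic per-class shuffle into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(fractions[0] * idx.size))
        n_val = int(round(fractions[1] * idx.size))
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return np.sort(train).astype(int), np.sort(val).astype(int), np.sort(test).astype(int)


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------


class TrainedModel:
    """The joint model plus the preprocessing statistics it was trained with."""

    def __init__(
        self,
        mode: str,
        class_names: tuple[str, ...],
        gcn: GCNEncoder | None = None,
        cnn: CNNEncoder | None = None,
        fusion: FusionHead | None = None,
        head_w: ad.Tensor | None = None,
        head_b: ad.Tensor | None = None,
        feat_norm: FeatureNormalizer | None = None,
        img_mean: np.ndarray | None = None,
        img_std: np.ndarray | None = None,
        pipeline: dict | None = None,
    ):
        self.mode = mode
        self.class_names = tuple(class_names)
        self.gcn = gcn
        self.cnn = cnn
        self.fusion = fusion
        self.head_w = head_w
        self.head_b = head_b
        self.feat_norm = feat_norm or FeatureNormalizer()
        self.img_mean = np.zeros(3) if img_mean is None else np.asarray(img_mean, dtype=np.float64)
        self.img_std = np.ones(3) if img_std is None else np.asarray(img_std, dtype=np.float64)
        self.pipeline = pipeline or {"k": DEFAULT_K, "d": DEFAULT_D, "image_size": 64}

    # -- forward -----------------------------------------------------------

    def _encode_graphs(self, samples: list[Sample]) -> ad.Tensor:
        embs = []
        for s in samples:
            feats = self.feat_norm.transform(s.feats) if s.feats.shape[0] else s.feats
            embs.append(self.gcn.encode(s.a_norm, feats))
        return ad.concat(embs, axis=0)

    def _encode_images(self, samples: list[Sample]) -> ad.Tensor:
        imgs = np.stack([s.image_small for s in samples])
        imgs = (imgs - self.img_mean[None, :, None, None]) / self.img_std[None, :, None, None]
        return self.cnn.encode(imgs)

    def forward(self, samples: list[Sample]) -> ad.Tensor:
        """Class logits for a list of samples.

        gcn_only consumes only the graph (node features + adjacency);
        cnn_only consumes only the tile image tensor; fused consumes both.
        """
        if self.mode == "gcn_only":
            return ad.linear(self._encode_graphs(samples), self.head_w, self.head_b)
        if self.mode == "cnn_only":
            return ad.linear(self._encode_images(samples), self.head_w, self.head_b)
        return self.fusion.forward(self._encode_graphs(samples), self._encode_images(samples))

    def predict_proba(self, samples: list[Sample], batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(samples), batch_size):
            logits = self.forward(samples[i : i + batch_size])
            out.append(ad.softmax(logits.data))
        return np.concatenate(out, axis=0)

    def predict(self, samples: list[Sample]) -> np.ndarray:
        return self.predict_proba(samples).argmax(axis=1)

    # -- parameters / persistence ------------------------------------------

    def named_parameters(self) -> list[tuple[str, ad.Tensor]]:
        named: list[tuple[str, ad.Tensor]] = []
        if self.gcn is not None:
            named += [(f"gcn_w{i}", w) for i, w in enumerate(self.gcn.weights)]
            named += [("gcn_wout", self.gcn.w_out), ("gcn_bout", self.gcn.b_out)]
        if self.cnn is not None:
            named += [(f"cnn_convw{i}", w) for i, w in enumerate(self.cnn.conv_w)]
            named += [(f"cnn_convb{i}", b) for i, b in enumerate(self.cnn.conv_b)]
            named += [("cnn_fcw", self.cnn.fc_w), ("cnn_fcb", self.cnn.fc_b)]
        if self.fusion is not None:
            f = self.fusion
            named += [
                ("fus_wc", f.w_c), ("fus_bc", f.b_c), ("fus_ws", f.w_s), ("fus_bs", f.b_s),
                ("fus_wgc", f.w_gate_c), ("fus_bgc", f.b_gate_c),
                ("fus_wgs", f.w_gate_s), ("fus_bgs", f.b_gate_s),
                ("fus_wcls", f.w_cls), ("fus_bcls", f.b_cls),
            ]
        if self.head_w is not None:
            named += [("head_w", self.head_w), ("head_b", self.head_b)]
        return named

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: all parameters + configs + normalization."""
        meta = {
            "mode": self.mode,
            "class_names": list(self.class_names),
            "pipeline": self.pipeline,
            "gcn_cfg": None if self.gcn is None else dataclasses.asdict(self.gcn.config),
            "cnn_cfg": None if self.cnn is None else dataclasses.asdict(self.cnn.config),
            "fusion_cfg": None if self.fusion is None else dataclasses.asdict(self.fusion.config),
            "fusion_dims": None if self.fusion is None else [self.fusion.dim_c, self.fusion.dim_s],
            "feat_mean": None if self.feat_norm.mean is None else self.feat_norm.mean.tolist(),
            "feat_std": None if self.feat_norm.std is None else self.feat_norm.std.tolist(),
            "img_mean": self.img_mean.tolist(),
            "img_std": self.img_std.tolist(),
        }
        arrays = {name: t.data for name, t in self.named_parameters()}
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as ckpt:
            meta = json.loads(str(ckpt["_meta"]))
            arrays = {k: ckpt[k] for k in ckpt.files if k != "_meta"}
        gcn = cnn = fusion = head_w = head_b = None
        if meta["gcn_cfg"]:
            cfg = dict(meta["gcn_cfg"])
            cfg["layer_widths"] = tuple(cfg["layer_widths"])
            gcn = GCNEncoder(GCNConfig(**cfg))
        if meta["cnn_cfg"]:
            cnn = CNNEncoder(CNNConfig(**meta["cnn_cfg"]))
        if meta["fusion_cfg"]:
            dim_c, dim_s = meta["fusion_dims"]
            fusion = FusionHead(dim_c, dim_s, FusionConfig(**meta["fusion_cfg"]))
        if "head_w" in arrays:
            head_w = ad.parameter(arrays["head_w"])
            head_b = ad.parameter(arrays["head_b"])
        model = cls(
            mode=meta["mode"],
            class_names=tuple(meta["class_names"]),
            gcn=gcn,
            cnn=cnn,
            fusion=fusion,
            head_w=head_w,
            head_b=head_b,
            feat_norm=FeatureNormalizer(
                mean=None if meta["feat_mean"] is None else np.asarray(meta["feat_mean"]),
                std=None if meta["feat_std"] is None else np.asarray(meta["feat_std"]),
            ),
            img_mean=np.asarray(meta["img_mean"]),
            img_std=np.asarray(meta["img_std"]),
            pipeline=meta["pipeline"],
        )
        for name, tensor in model.named_parameters():
            tensor.data = arrays[name].astype(np.float64)
        return model


@dataclasses.dataclass
class TrainResult:
    model: TrainedModel
    log: pd.DataFrame
    split: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _fit_normalization(samples: list[Sample], train_idx: np.ndarray):
    feats = [samples[i].feats for i in train_idx if samples[i].feats.shape[0]]
    norm = FeatureNormalizer().fit(np.concatenate(feats, axis=0)) if feats else FeatureNormalizer(
        mean=np.zeros(samples[0].feats.shape[1]), std=np.ones(samples[0].feats.shape[1])
    )
    imgs = np.stack([samples[i].image_small for i in train_idx])
    img_mean = imgs.mean(axis=(0, 2, 3))
    img_std = imgs.std(axis=(0, 2, 3))
    img_std[img_std < 1e-12] = 1.0
    return norm, img_mean, img_std


def init_model(
    mode: str,
    class_names: tuple[str, ...],
    feat_dim: int,
    seed: int = 0,
    gcn_config: GCNConfig | None = None,
    cnn_config: CNNConfig | None = None,
    fusion_config: FusionConfig | None = None,
    pretrained: tuple[TrainedModel | None, TrainedModel | None] | None = None,
    pipeline: dict | None = None,
) -> TrainedModel:
    """Randomly initialized model for a mode (Glorot weights, zero biases)."""
    pipeline = pipeline or {"k": DEFAULT_K, "d": DEFAULT_D, "image_size": 64}
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    n_classes = len(class_names)
    gcn = cnn = fusion = head_w = head_b = None
    rng = np.random.default_rng(int(seeds[0]))
    if mode in ("gcn_only", "fused"):
        if pretrained and pretrained[0] is not None:
            gcn = pretrained[0].gcn
        else:
            cfg = gcn_config or GCNConfig(layer_widths=(feat_dim, 32, 32), seed=int(seeds[1]))
            gcn = GCNEncoder(cfg)
    if mode in ("cnn_only", "fused"):
        if pretrained and pretrained[1] is not None:
            cnn = pretrained[1].cnn
        else:
            cnn = CNNEncoder(cnn_config or CNNConfig(seed=int(seeds[2])))
    if mode == "fused":
        fcfg = fusion_config or FusionConfig(n_classes=n_classes, seed=int(seeds[3]))
        fusion = FusionHead(gcn.config.embed_dim, cnn.config.out_dim, fcfg)
    else:
        in_dim = gcn.config.embed_dim if mode == "gcn_only" else cnn.config.out_dim
        head_w = ad.parameter(ad.glorot_uniform(rng, (in_dim, n_classes)))
        head_b = ad.parameter(np.zeros(n_classes))
    return TrainedModel(
        mode=mode, class_names=class_names, gcn=gcn, cnn=cnn, fusion=fusion,
        head_w=head_w, head_b=head_b, pipeline=pipeline,
    )


def train(
    samples: list[Sample],
    labels: np.ndarray,
    class_names: tuple[str, ...],
    tcfg: TrainConfig | None = None,
    gcn_config: GCNConfig | None = None,
    cnn_config: CNNConfig | None = None,
    fusion_config: FusionConfig | None = None,
    pretrained: tuple[TrainedModel | None, TrainedModel | None] | None = None,
    pipeline: dict | None = None,
) -> TrainResult:
    """Train in the requested mode on a prepared sample list.

    ``mode="fused"`` without ``pretrained`` runs the full two-stage
    protocol: both branches are trained separately first, then fine-tuned
    jointly with the fusion head.  ``pretrained=(gcn_model, cnn_model)``
    skips the branch stage (models from earlier ``gcn_only`` /
    ``cnn_only`` runs).
    """
    tcfg = tcfg or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least 2 classes")
    train_idx, val_idx, test_idx = stratified_split(labels, tcfg.split, tcfg.seed)
    split = {"train": train_idx, "val": val_idx, "test": test_idx}
    pipeline = pipeline or {"k": DEFAULT_K, "d": DEFAULT_D, "image_size": 64}

    if tcfg.mode == "fused" and pretrained is None:
        branch = {}
        for mode in ("gcn_only", "cnn_only"):
            res = train(
                samples, labels, class_names,
                dataclasses.replace(tcfg, mode=mode),
                gcn_config=gcn_config, cnn_config=cnn_config, pipeline=pipeline,
            )
            branch[mode] = res.model
        pretrained = (branch["gcn_only"], branch["cnn_only"])

    model = init_model(
        tcfg.mode, class_names, samples[0].feats.shape[1], tcfg.seed,
        gcn_config, cnn_config, fusion_config, pretrained, pipeline,
    )
    if pretrained and pretrained[0] is not None:
        model.feat_norm = pretrained[0].feat_norm
        model.img_mean, model.img_std = pretrained[0].img_mean, pretrained[0].img_std
        if pretrained[1] is not None:
            model.img_mean, model.img_std = pretrained[1].img_mean, pretrained[1].img_std
    else:
        model.feat_norm, model.img_mean, model.img_std = _fit_normalization(samples, train_idx)

    if tcfg.mode == "fused":
        encoder_params = (model.gcn.parameters if model.gcn else []) + (
            model.cnn.parameters if model.cnn else []
        )
        groups = [
            {"params": model.fusion.parameters, "lr": tcfg.lr},
            {"params": encoder_params, "lr": tcfg.finetune_lr if pretrained else tcfg.lr},
        ]
        opt = ad.Adam(groups)
    else:
        opt = ad.Adam([p for _, p in model.named_parameters()], lr=tcfg.lr)

    shuffle_rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 17]).generate_state(1)[0] % (2**31))
    log_rows = []
    for epoch in range(tcfg.epochs):
        perm = shuffle_rng.permutation(train_idx.size)
        order = train_idx[perm]
        losses = []
        for start in range(0, order.size, tcfg.batch_size):
            batch = order[start : start + tcfg.batch_size]
            logits = model.forward([samples[i] for i in batch])
            loss = ad.softmax_cross_entropy(logits, labels[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}: aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if val_idx.size:
            val_acc = float((model.predict([samples[i] for i in val_idx]) == labels[val_idx]).mean())
        else:
            val_acc = np.nan
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
    log = pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_accuracy"])
    return TrainResult(model=model, log=log, split=split)


def train_from_manifest(
    manifest: pd.DataFrame | str | Path,
    root: str | Path | None = None,
    tcfg: TrainConfig | None = None,
    **kwargs,
) -> TrainResult:
    """Convenience wrapper: load tiles/masks from a manifest CSV and train."""
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        root = root or manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    pipeline = kwargs.pop("pipeline", None) or {"k": DEFAULT_K, "d": DEFAULT_D, "image_size": 64}
    samples, labels, class_names = load_samples(
        manifest, root, k=pipeline["k"], d=pipeline["d"], image_size=pipeline["image_size"]
    )
    return train(samples, labels, class_names, tcfg=tcfg, pipeline=pipeline, **kwargs)


def evaluate(
    model: TrainedModel,
    samples: list[Sample],
    labels: np.ndarray,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Metrics report plus a per-tile prediction table (tile, true, pred, prob_*)."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = model.predict_proba(samples)
    preds = probs.argmax(axis=1)
    report = compute_metrics(labels, preds, len(model.class_names), model.class_names)
    rows = {
        "tile": [s.name for s in samples],
        "true": [model.class_names[t] for t in labels],
        "pred": [model.class_names[p] for p in preds],
    }
    for c in range(probs.shape[1]):
        rows[f"prob_{c}"] = probs[:, c]
    return report, pd.DataFrame(rows)
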