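"""End-to-end orchestration: contrastive tower training, classifier training,
cross-validated evaluation, the one-encoder ablation and frame inference.

The default ("two-tower") path trains the image and text towers, their
modality-specific transformer encoders and projection heads with the
multimodal contrastive loss, then freezes them and trains the MLP phase
classifier on the concatenated joint representations with cross-entropy.
The ablation ("one-tower") path concatenates the raw modality sequences,
runs a single shared encoder and trains encoder + classifier jointly with
cross-entropy — no contrastive stage.

All randomness flows from one master seed; identical (data, config, seed)
reproduce identical loss traces and metrics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .embedders import ImageTower, TextTower, TowerConfig, build_vocab, tokenize
from .encoders import (
    EncoderConfig,
    TransformerEncoder,
    attention_mask,
    masked_mean,
)
from .evalstats import (
    EvalReport,
    aggregate_folds,
    evaluate_predictions,
    kfold_split,
    paired_t_test,
)
from .exceptions import ConfigurationError
from .fusion import MLPClassifier, PhasePrediction, ProjectionHead, softmax
from .objectives import (
    cross_entropy_logits,
    lr_schedule,
    multimodal_contrastive_loss,
)

N_PHASES = 7


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 9973 + k * 7919 + 17) % (2**31 - 1)


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings.

    Full-scale defaults follow the published recipe (SGD, lr 0.001, weight
    decay 1e-5, 50 epochs with a 5-epoch warmup and cosine-annealed decay);
    `desk_preset` shortens and rescales for from-scratch CPU training.
    """

    base_lr: float = 0.001
    weight_decay: float = 1e-5
    epochs: int = 50
    warmup_epochs: int = 5
    batch_size: int = 16
    tau: float = 0.1
    floor_lr: float = 0.0
    symmetric: bool = False
    classifier_epochs: int = 80
    classifier_lr: float = 0.2
    classifier_batch: int = 64
    seed: int = 0
    mode: str = "two_tower"

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ConfigurationError("base_lr must be > 0")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")
        if self.warmup_epochs >= self.epochs:
            raise ConfigurationError("warmup_epochs must be < epochs")
        if self.mode == "two_tower" and self.batch_size < 2:
            raise ConfigurationError(
                "contrastive training needs batch_size >= 2 (n=1 gives 0 loss)"
            )

    @classmethod
    def desk_preset(cls, seed: int = 0, **overrides) -> "TrainConfig":
        kw = dict(base_lr=0.02, epochs=30, warmup_epochs=2, batch_size=16,
                  seed=seed)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------- the models
class TwoTowerModel(nn.Module):
    """Towers + per-modality encoders + per-modality projection heads."""

    def __init__(self, vocab: dict, tower_config: TowerConfig | None = None,
                 encoder_config: EncoderConfig | None = None,
                 d_joint: int | None = None, seed: int = 0):
        tc = tower_config or TowerConfig.desk_preset(seed=seed)
        ec = encoder_config or EncoderConfig.desk_preset(
            seed=_derive_seed(seed, 2), d_model=tc.d_out
        )
        if ec.d_model != tc.d_out:
            raise ConfigurationError(
                f"encoder d_model {ec.d_model} != tower d_out {tc.d_out}"
            )
        self.tower_config = tc
        self.encoder_config = ec
        self.d_joint = d_joint or tc.d_out
        self.vocab = vocab
        self.image_tower = ImageTower(
            dataclasses.replace(tc, seed=_derive_seed(seed, 0))
        )
        self.text_tower = TextTower(
            dataclasses.replace(tc, seed=_derive_seed(seed, 1)), vocab
        )
        self.image_encoder = TransformerEncoder(
            dataclasses.replace(ec, seed=_derive_seed(seed, 3))
        )
        self.text_encoder = TransformerEncoder(
            dataclasses.replace(ec, seed=_derive_seed(seed, 4))
        )
        rng = np.random.default_rng(_derive_seed(seed, 5))
        self.image_head = ProjectionHead(tc.d_out, self.d_joint, rng)
        self.text_head = ProjectionHead(tc.d_out, self.d_joint, rng)
        self.training = False

    def forward_images(self, frames: np.ndarray) -> nn.Tensor:
        """(B, H, W, C) -> projected image vectors (B, d_joint)."""
        x = self.image_tower.forward(frames)
        x = self.image_encoder.forward(x)
        return self.image_head(masked_mean(x))

    def forward_texts(self, ids: np.ndarray, lengths: np.ndarray) -> nn.Tensor:
        """Padded token ids (B, L) -> projected text vectors (B, d_joint)."""
        x = self.text_tower.forward(ids)
        mask = attention_mask(lengths, ids.shape[1])
        x = self.text_encoder.forward(x, mask)
        return self.text_head(masked_mean(x, lengths))


class OneTowerModel(nn.Module):
    """Ablation: one shared encoder over the concatenated modality sequences."""

    def __init__(self, vocab: dict, tower_config: TowerConfig | None = None,
                 encoder_config: EncoderConfig | None = None, seed: int = 0):
        tc = tower_config or TowerConfig.desk_preset(seed=seed)
        ec = encoder_config or EncoderConfig.desk_preset(
            seed=_derive_seed(seed, 12), d_model=tc.d_out
        )
        self.tower_config = tc
        self.encoder_config = ec
        self.vocab = vocab
        self.image_tower = ImageTower(
            dataclasses.replace(tc, seed=_derive_seed(seed, 10))
        )
        self.text_tower = TextTower(
            dataclasses.replace(tc, seed=_derive_seed(seed, 11)), vocab
        )
        self.encoder = TransformerEncoder(
            dataclasses.replace(ec, seed=_derive_seed(seed, 13))
        )
        self.training = False

    def forward(self, frames, ids, lengths) -> nn.Tensor:
        """Concatenate image (first) and text sequences, encode, mean-pool."""
        xi = self.image_tower.forward(frames)
        xt = self.text_tower.forward(ids)
        n_patches = xi.shape[1]
        x = nn.concat([xi, xt], axis=1)
        total = np.asarray(lengths) + n_patches
        h = self.encoder.forward(x, attention_mask(total, x.shape[1]))
        return masked_mean(h, total)


# -------------------------------------------------------------- data helpers
def pad_token_lists(token_lists):
    lengths = np.array([len(t) for t in token_lists])
    max_len = int(lengths.max())
    ids = np.zeros((len(token_lists), max_len), dtype=np.int64)
    for i, toks in enumerate(token_lists):
        ids[i, : len(toks)] = toks
    return ids, lengths


def prepare_arrays(dataset, manifest, vocab):
    """Stack frames/token lists/labels for the given manifest rows."""
    frames = np.stack(
        [dataset.frame(r.video_id, r.frame_index) for r in manifest.itertuples()]
    )
    token_lists = [tokenize(t, vocab) for t in manifest["text"]]
    labels = manifest["phase_id"].to_numpy()
    return frames, token_lists, labels


# ------------------------------------------------------------------ training
def train_towers(frames, token_lists, model: TwoTowerModel, cfg: TrainConfig):
    """Contrastive tower training; returns the per-epoch mean loss trace."""
    n = len(frames)
    if n < cfg.batch_size:
        raise ValueError("dataset smaller than one batch")
    rng = np.random.default_rng(_derive_seed(cfg.seed, 21))
    opt = nn.SGD(model.parameters(), lr=0.0, weight_decay=cfg.weight_decay)
    steps_per_epoch = n // cfg.batch_size
    model.set_training(True)
    trace, step = [], 0
    for _ in range(cfg.epochs):
        idx = rng.permutation(n)
        losses = []
        for b0 in range(0, steps_per_epoch * cfg.batch_size, cfg.batch_size):
            sel = idx[b0 : b0 + cfg.batch_size]
            ids, lengths = pad_token_lists([token_lists[i] for i in sel])
            opt.lr = lr_schedule(step, cfg.base_lr, cfg.warmup_epochs,
                                 cfg.epochs, steps_per_epoch, cfg.floor_lr)
            xi = model.forward_images(frames[sel])
            xt = model.forward_texts(ids, lengths)
            loss = multimodal_contrastive_loss(xi, xt, cfg.tau, cfg.symmetric)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
        trace.append(float(np.mean(losses)))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("non-finite training loss")
    model.set_training(False)
    return trace


def compute_joint_features(model: TwoTowerModel, frames, token_lists,
                           batch_size: int = 64) -> np.ndarray:
    """Frozen-tower joint representations (image part first)."""
    feats = []
    for b0 in range(0, len(frames), batch_size):
        fr = frames[b0 : b0 + batch_size]
        ids, lengths = pad_token_lists(token_lists[b0 : b0 + batch_size])
        xi = model.forward_images(fr).data
        xt = model.forward_texts(ids, lengths).data
        feats.append(np.concatenate([xi, xt], axis=1))
    return np.concatenate(feats, axis=0)


def train_classifier(features, labels, cfg: TrainConfig,
                     mlp: MLPClassifier | None = None):
    """Cross-entropy SGD training of the MLP on frozen joint features."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= N_PHASES:
        raise ValueError("phase labels must lie in [0, 7)")
    rng = np.random.default_rng(_derive_seed(cfg.seed, 31))
    if mlp is None:
        mlp = MLPClassifier(features.shape[1],
                            np.random.default_rng(_derive_seed(cfg.seed, 32)))
    opt = nn.SGD(mlp.parameters(), lr=cfg.classifier_lr,
                 weight_decay=cfg.weight_decay)
    n = len(features)
    trace = []
    for _ in range(cfg.classifier_epochs):
        idx = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.classifier_batch):
            sel = idx[b0 : b0 + cfg.classifier_batch]
            loss = cross_entropy_logits(
                mlp.logits(nn.constant(features[sel])), labels[sel]
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return mlp, trace


def train_one_tower(frames, token_lists, labels, model: OneTowerModel,
                    mlp: MLPClassifier, cfg: TrainConfig):
    """Joint cross-entropy training of the single-encoder ablation model."""
    n = len(frames)
    rng = np.random.default_rng(_derive_seed(cfg.seed, 41))
    params = model.parameters() + mlp.parameters()
    opt = nn.SGD(params, lr=0.0, weight_decay=cfg.weight_decay)
    steps_per_epoch = max(n // cfg.batch_size, 1)
    model.set_training(True)
    trace, step = [], 0
    for _ in range(cfg.epochs):
        idx = rng.permutation(n)
        losses = []
        for b0 in range(0, steps_per_epoch * cfg.batch_size, cfg.batch_size):
            sel = idx[b0 : b0 + cfg.batch_size]
            ids, lengths = pad_token_lists([token_lists[i] for i in sel])
            opt.lr = lr_schedule(step, cfg.base_lr, cfg.warmup_epochs,
                                 cfg.epochs, steps_per_epoch, cfg.floor_lr)
            pooled = model.forward(frames[sel], ids, lengths)
            loss = cross_entropy_logits(mlp.logits(pooled), labels[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
        trace.append(float(np.mean(losses)))
    model.set_training(False)
    return trace


# ---------------------------------------------------------------- evaluation
def predict_two_tower(model, mlp, frames, token_lists) -> np.ndarray:
    feats = compute_joint_features(model, frames, token_lists)
    return mlp.predict_proba(feats).argmax(axis=1)


def predict_one_tower(model, mlp, frames, token_lists,
                      batch_size: int = 64) -> np.ndarray:
    preds = []
    for b0 in range(0, len(frames), batch_size):
        ids, lengths = pad_token_lists(token_lists[b0 : b0 + batch_size])
        pooled = model.forward(frames[b0 : b0 + batch_size], ids, lengths).data
        preds.append(mlp.predict_proba(pooled).argmax(axis=1))
    return np.concatenate(preds)


def retrieval_accuracy(model: TwoTowerModel, frames, token_lists, labels,
                       rng, n_groups: int = 20) -> float:
    """Phase-level in-batch top-1 cross-modal retrieval.

    Candidate sets hold one (frame, text) pair per phase, so exact-pair and
    phase-level matching coincide; chance level is 1/7.
    """
    labels = np.asarray(labels)
    by_phase = {p: np.flatnonzero(labels == p) for p in range(N_PHASES)}
    by_phase = {p: v for p, v in by_phase.items() if len(v)}
    hits, total = 0, 0
    for _ in range(n_groups):
        sel = np.array([rng.choice(v) for v in by_phase.values()])
        ids, lengths = pad_token_lists([token_lists[i] for i in sel])
        xi = model.forward_images(frames[sel]).data
        xt = model.forward_texts(ids, lengths).data
        xi = xi / np.linalg.norm(xi, axis=1, keepdims=True)
        xt = xt / np.linalg.norm(xt, axis=1, keepdims=True)
        sims = xi @ xt.T
        hits += int((sims.argmax(axis=1) == np.arange(len(sel))).sum())
        total += len(sel)
    return hits / total


# ------------------------------------------------------------ cross-val runs
@dataclasses.dataclass
class CrossvalResult:
    fold_reports: list
    aggregate: dict
    fold_plan: object
    tower_traces: list
    classifier_traces: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "aggregate": self.aggregate,
                "folds": [r.to_dict() for r in self.fold_reports],
            },
            indent=2,
        )


def _fit_two_tower_fold(dataset, train_manifest, cfg, fold_seed):
    vocab = build_vocab(train_manifest["text"])
    model = TwoTowerModel(vocab, seed=fold_seed)
    frames, toks, labels = prepare_arrays(dataset, train_manifest, vocab)
    fold_cfg = dataclasses.replace(cfg, seed=fold_seed)
    tower_trace = train_towers(frames, toks, model, fold_cfg)
    feats = compute_joint_features(model, frames, toks)
    mlp, clf_trace = train_classifier(feats, labels, fold_cfg)
    return model, mlp, vocab, tower_trace, clf_trace


def run_crossval(dataset, cfg: TrainConfig, k: int = 5) -> CrossvalResult:
    """Video-level k-fold cross-validation of the two-tower pipeline."""
    plan = kfold_split(dataset.video_ids, k=k, seed=_derive_seed(cfg.seed, 51))
    reports, tower_traces, clf_traces = [], [], []
    for fold in range(k):
        train_m = dataset.subset(plan.train_videos(fold))
        test_m = dataset.subset(plan.fold_videos(fold))
        assert not set(test_m["video_id"]) & set(train_m["video_id"])
        fold_seed = _derive_seed(cfg.seed, 100 + fold)
        model, mlp, vocab, ttr, ctr = _fit_two_tower_fold(
            dataset, train_m, cfg, fold_seed
        )
        frames, toks, labels = prepare_arrays(dataset, test_m, vocab)
        preds = predict_two_tower(model, mlp, frames, toks)
        reports.append(evaluate_predictions(labels, preds, fold_id=fold))
        tower_traces.append(ttr)
        clf_traces.append(ctr)
    return CrossvalResult(
        fold_reports=reports,
        aggregate=aggregate_folds(reports),
        fold_plan=plan,
        tower_traces=tower_traces,
        classifier_traces=clf_traces,
    )


@dataclasses.dataclass
class AblationResult:
    two_tower_acc: list  # per fold
    one_tower_acc: list
    t_test: object
    fold_plan: object


def run_ablation(dataset, cfg: TrainConfig, k: int = 5) -> AblationResult:
    """Two-encoder vs one-encoder comparison on identical fold plans/seeds."""
    plan = kfold_split(dataset.video_ids, k=k, seed=_derive_seed(cfg.seed, 51))
    acc2, acc1 = [], []
    for fold in range(k):
        train_m = dataset.subset(plan.train_videos(fold))
        test_m = dataset.subset(plan.fold_videos(fold))
        fold_seed = _derive_seed(cfg.seed, 100 + fold)
        fold_cfg = dataclasses.replace(cfg, seed=fold_seed)

        model2, mlp2, vocab, _, _ = _fit_two_tower_fold(
            dataset, train_m, cfg, fold_seed
        )
        frames_te, toks_te, labels_te = prepare_arrays(dataset, test_m, vocab)
        preds = predict_two_tower(model2, mlp2, frames_te, toks_te)
        acc2.append(float((preds == labels_te).mean()))

        model1 = OneTowerModel(vocab, seed=fold_seed)
        mlp1 = MLPClassifier(
            model1.encoder_config.d_model,
            np.random.default_rng(_derive_seed(fold_seed, 33)),
        )
        frames_tr, toks_tr, labels_tr = prepare_arrays(dataset, train_m, vocab)
        train_one_tower(frames_tr, toks_tr, labels_tr, model1, mlp1, fold_cfg)
        preds1 = predict_one_tower(model1, mlp1, frames_te, toks_te)
        acc1.append(float((preds1 == labels_te).mean()))
    return AblationResult(
        two_tower_acc=acc2,
        one_tower_acc=acc1,
        t_test=paired_t_test(acc2, acc1),
        fold_plan=plan,
    )


# ----------------------------------------------------------------- inference
@dataclasses.dataclass
class ModelBundle:
    model: TwoTowerModel
    mlp: MLPClassifier
    vocab: dict
    canonical_texts: list

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        state = {}
        for key, val in self.model.state_dict().items():
            state[f"model.{key}"] = val
        for key, val in self.mlp.state_dict().items():
            state[f"mlp.{key}"] = val
        np.savez(out / "weights.npz", **state)
        meta = {
            "vocab": self.vocab,
            "canonical_texts": self.canonical_texts,
            "tower_config": dataclasses.asdict(self.model.tower_config),
            "encoder_config": dataclasses.asdict(self.model.encoder_config),
            "d_joint": self.model.d_joint,
            "mlp_hidden": self.mlp.fc1.w.shape[1],
        }
        (out / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir) -> "ModelBundle":
        src = Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        model = TwoTowerModel(
            meta["vocab"],
            tower_config=TowerConfig(**meta["tower_config"]),
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            d_joint=meta["d_joint"],
        )
        mlp = MLPClassifier(2 * meta["d_joint"], np.random.default_rng(0),
                            d_hidden=meta["mlp_hidden"])
        with np.load(src / "weights.npz") as state:
            model.load_state_dict(
                {k[len("model."):]: state[k] for k in state.files
                 if k.startswith("model.")}
            )
            mlp.load_state_dict(
                {k[len("mlp."):]: state[k] for k in state.files
                 if k.startswith("mlp.")}
            )
        return cls(model=model, mlp=mlp, vocab=meta["vocab"],
                   canonical_texts=meta["canonical_texts"])


def infer_frames(frames: np.ndarray, bundle: ModelBundle,
                 inference_mode: str = "canonical-scan") -> list:
    """Classify frames without known paired texts.

    canonical-scan: pair each frame with each of the 7 canonical phase texts
    and keep, for each hypothesised phase, the probability the classifier
    assigns to that phase; the prediction is the best-supported hypothesis.
    fixed-text: pair every frame with one neutral text and classify directly.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 3:
        frames = frames[None]
    b = len(frames)
    xi = bundle.model.forward_images(frames).data
    if inference_mode == "fixed-text":
        toks = [tokenize("laparoscopic surgical video frame", bundle.vocab)] * b
        ids, lengths = pad_token_lists(toks)
        xt = bundle.model.forward_texts(ids, lengths).data
        probs = bundle.mlp.predict_proba(np.concatenate([xi, xt], axis=1))
    elif inference_mode == "canonical-scan":
        scores = np.empty((b, N_PHASES))
        for t, text in enumerate(bundle.canonical_texts):
            toks = [tokenize(text, bundle.vocab)] * b
            ids, lengths = pad_token_lists(toks)
            xt = bundle.model.forward_texts(ids, lengths).data
            p = bundle.mlp.predict_proba(np.concatenate([xi, xt], axis=1))
            scores[:, t] = p[:, t]
        probs = scores / scores.sum(axis=1, keepdims=True)
    else:
        raise ConfigurationError(f"unknown inference_mode {inference_mode!r}")
    return [
        PhasePrediction(probabilities=row, predicted_phase=int(row.argmax()))
        for row in probs
    ]


def infer_paths(paths, bundle: ModelBundle,
                inference_mode: str = "canonical-scan"):
    """Classify image files; unreadable files are warned about and skipped."""
    import warnings

    from PIL import Image

    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input frames")
    kept, frames = [], []
    for p in paths:
        try:
            arr = np.asarray(Image.open(p).convert("RGB"),
                             dtype=np.float64) / 255.0
        except Exception as exc:  # unreadable image: warn, continue
            warnings.warn(f"skipping {p}: {exc}", stacklevel=2)
            continue
        kept.append(p)
        frames.append(arr)
    if not frames:
        raise ValueError("no readable frames")
    preds = infer_frames(np.stack(frames), bundle, inference_mode)
    return list(zip(kept, preds))


def fit_bundle(dataset, cfg: TrainConfig) -> ModelBundle:
    """Train towers + classifier on the dataset's train split."""
    train_m = dataset.manifest[dataset.manifest["split"] == "train"]
    model, mlp, vocab, _, _ = _fit_two_tower_fold(
        dataset, train_m.reset_index(drop=True), cfg, cfg.seed
    )
    return ModelBundle(
        model=model, mlp=mlp, vocab=vocab,
        canonical_texts=[p.canonical_text for p in dataset.catalog.phases],
    )
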