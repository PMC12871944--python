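"""Contrastive pretraining and supervised fine-tuning of user-day encoders.

Pretraining is fully self-supervised: triplets (anchor = one user-day,
positive = same user on a different day, negative = a different user) train
a 2-layer MLP encoder plus 2-layer projection head under the triplet margin
loss, pulling a user's days together in embedding space and pushing
different users apart. No outcome labels are used.

For classification the encoder is frozen and a fresh 2-layer MLP head is
trained on its embeddings with weighted binary cross-entropy (inverse class
frequency weights). Day-level probabilities are averaged per user to give a
single user-level prediction. A no-pretraining ablation trains the same
architecture end-to-end under supervision only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


class SamplingError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class PretrainConfig:
    margin: float = 1.0
    lr: float = 1e-3
    epochs: int = 3
    batch: int = 256
    #: sampled-triplet batches per epoch, as a multiple of ceil(n_rows/batch);
    #: the triplet count per epoch is a free protocol choice
    epoch_scale: int = 1
    encoder_widths: tuple[int, int] = (128, 64)
    projection_widths: tuple[int, int] = (64, 32)
    seed: int = 0

    def validate(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if len(self.encoder_widths) < 2 or len(self.projection_widths) < 2:
            raise ValueError("encoder and projection head need >= 2 layers")
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be >= 1")


@dataclass
class FinetuneConfig:
    lr: float = 1e-3
    epochs: int = 20
    batch: int = 1024
    head_hidden: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be >= 1")


@dataclass
class EncoderState:
    params: nn.Params
    input_dim: int
    widths: tuple[int, ...]
    config: PretrainConfig
    pretrained: bool = True
    diagnostics: dict = field(default_factory=dict)

    def encode(self, x: np.ndarray) -> np.ndarray:
        out, _ = nn.mlp_forward(self.params, np.asarray(x, dtype=float))
        return out


@dataclass
class ClassifierState:
    encoder_params: nn.Params
    head_params: nn.Params
    outcome: str
    pretrained: bool
    config: FinetuneConfig
    #: training-set standardization of the frozen rectified embedding
    #: (None for the end-to-end ablation, whose encoder is part of the head
    #: chain)
    emb_mean: np.ndarray | None = None
    emb_sd: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def full_params(self) -> nn.Params:
        return list(self.encoder_params) + list(self.head_params)

    def decision_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.emb_mean is None:
            out, _ = nn.mlp_forward(self.full_params, x)
            return out.ravel()
        emb, _ = nn.mlp_forward(self.encoder_params, x)
        h = (np.maximum(emb, 0.0) - self.emb_mean) / self.emb_sd
        out, _ = nn.mlp_forward(self.head_params, h)
        return out.ravel()


# ---------------------------------------------------------------------------
# Triplet sampling
# ---------------------------------------------------------------------------

class _UserIndex:
    """Row indices grouped by user, in first-appearance user order."""

    def __init__(self, user_ids: np.ndarray):
        user_ids = np.asarray(user_ids)
        self.users, inverse = np.unique(user_ids, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        self.sorted_rows = order
        self.counts = np.bincount(inverse, minlength=len(self.users))
        self.offsets = np.concatenate([[0], np.cumsum(self.counts)])

    def row(self, user_idx: np.ndarray, within: np.ndarray) -> np.ndarray:
        return self.sorted_rows[self.offsets[user_idx] + within]


def sample_triplets(
    user_ids: np.ndarray, rng: np.random.Generator, n_triplets: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized label-free triplet sampling over training rows.

    Anchor users are drawn uniformly among users with >= 2 rows; the
    positive is a different row of the same user; the negative is a row of
    a uniformly drawn different user. Returns (anchor, positive, negative)
    row-index arrays.
    """
    idx = _UserIndex(user_ids)
    n_users = len(idx.users)
    if n_users < 2:
        raise SamplingError("triplet sampling needs at least 2 users")
    eligible = np.flatnonzero(idx.counts >= 2)
    if len(eligible) == 0:
        raise SamplingError("no user has >= 2 rows; cannot form anchor/positive pairs")

    a_user = eligible[rng.integers(0, len(eligible), size=n_triplets)]
    ca = idx.counts[a_user]
    a_within = rng.integers(0, ca)
    # positive: uniform over the user's other rows (shift past the anchor)
    p_within = rng.integers(0, ca - 1)
    p_within = p_within + (p_within >= a_within)
    # negative user: uniform over all *other* users
    n_user = rng.integers(0, n_users - 1, size=n_triplets)
    n_user = n_user + (n_user >= a_user)
    n_within = rng.integers(0, idx.counts[n_user])
    return idx.row(a_user, a_within), idx.row(a_user, p_within), idx.row(n_user, n_within)


def sample_triplet(user_ids: np.ndarray, rng: np.random.Generator) -> tuple[int, int, int]:
    """Single-triplet convenience wrapper around :func:`sample_triplets`."""
    a, p, n = sample_triplets(user_ids, rng, 1)
    return int(a[0]), int(p[0]), int(n[0])


# ---------------------------------------------------------------------------
# Pretraining
# ---------------------------------------------------------------------------

def pretrain_encoder(
    x: np.ndarray, user_ids: np.ndarray, cfg: PretrainConfig | None = None
) -> EncoderState:
    """Train encoder + projection head with the batch triplet margin loss.

    Triplets are re-sampled every step; one epoch is epoch_scale *
    ceil(n_rows / batch) batches, so the default setup sees a few thousand
    sampled triplets over the course of pretraining. The projection head is
    discarded: only the encoder is returned for downstream use.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or PretrainConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    rng = np.random.default_rng(cfg.seed)
    enc_widths = [d, *cfg.encoder_widths]
    proj_widths = [cfg.encoder_widths[-1], *cfg.projection_widths]
    enc = nn.mlp_init(enc_widths, rng)
    proj = nn.mlp_init(proj_widths, rng)
    n_enc = len(enc)

    eval_trip = sample_triplets(user_ids, rng, min(2048, max(4 * n, 64)))

    def eval_loss(enc_p, proj_p) -> float:
        full = list(enc_p) + list(proj_p)
        za, _ = nn.mlp_forward(full, x[eval_trip[0]])
        zp, _ = nn.mlp_forward(full, x[eval_trip[1]])
        zn, _ = nn.mlp_forward(full, x[eval_trip[2]])
        return nn.triplet_margin_loss(za, zp, zn, cfg.margin)

    init_loss = eval_loss(enc, proj)
    params = list(enc) + list(proj)
    opt = nn.Adam(params, lr=cfg.lr)
    steps_per_epoch = cfg.epoch_scale * int(np.ceil(n / cfg.batch))
    for _ in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            ia, ip, in_ = sample_triplets(user_ids, rng, cfg.batch)
            batch = np.concatenate([x[ia], x[ip], x[in_]], axis=0)
            out, cache = nn.mlp_forward(params, batch)
            b = len(ia)
            loss, da, dp, dn = nn.triplet_margin_loss_grads(
                out[:b], out[b:2 * b], out[2 * b:], cfg.margin
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite triplet loss ({loss}) during pretraining")
            dout = np.concatenate([da, dp, dn], axis=0)
            grads, _ = nn.mlp_backward(params, cache, dout)
            params = opt.step(params, grads)

    enc_final = params[:n_enc]
    final_loss = eval_loss(enc_final, params[n_enc:])
    return EncoderState(
        params=enc_final, input_dim=d, widths=tuple(enc_widths), config=cfg,
        pretrained=True,
        diagnostics={"init_loss": init_loss, "final_loss": final_loss},
    )


def init_encoder(input_dim: int, cfg: PretrainConfig | None = None) -> EncoderState:
    """Untrained (randomly initialized) encoder with the same architecture."""
    cfg = cfg or PretrainConfig()
    rng = np.random.default_rng(cfg.seed)
    widths = [input_dim, *cfg.encoder_widths]
    return EncoderState(params=nn.mlp_init(widths, rng), input_dim=input_dim,
                        widths=tuple(widths), config=cfg, pretrained=False)


def compactness_ratio(embeddings: np.ndarray, user_ids: np.ndarray) -> float:
    """Mean within-user / mean between-user pairwise embedding distance.

    Lower values mean a user's days cluster more tightly relative to the
    spread between users."""
    embeddings = np.asarray(embeddings, dtype=float)
    user_ids = np.asarray(user_ids)
    diff = embeddings[:, None, :] - embeddings[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    same = (user_ids[:, None] == user_ids[None, :])
    off_diag = ~np.eye(len(embeddings), dtype=bool)
    within = dist[same & off_diag]
    between = dist[~same]
    if len(within) == 0 or len(between) == 0:
        raise ValueError("need both within-user and between-user pairs")
    return float(within.mean() / between.mean())


# ---------------------------------------------------------------------------
# Supervised fine-tuning
# ---------------------------------------------------------------------------

def compute_class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights, normalized to average 1."""
    labels = np.asarray(labels).astype(int)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present in the training fold")
    inv = {c: 1.0 / counts[c] for c in (0, 1)}
    mean_inv = (inv[0] + inv[1]) / 2.0
    return {c: inv[c] / mean_inv for c in (0, 1)}


def finetune_classifier(
    encoder: EncoderState,
    x: np.ndarray,
    labels: np.ndarray,
    cfg: FinetuneConfig | None = None,
    outcome: str = "",
) -> ClassifierState:
    """Train a 2-layer classification head on the frozen encoder.

    Only head weights change — the returned state's encoder parameters are
    bit-identical to the input encoder's. Uses weighted BCE-with-logits and
    Adam; deterministic given ``cfg.seed``.
    """
    cfg = cfg or FinetuneConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    weights = compute_class_weights(y)
    w = np.where(y > 0.5, weights[1], weights[0])

    # frozen encoder: embed once; the head sees the rectified embedding,
    # standardized with training-set statistics so the head's fixed training
    # budget is insensitive to the embedding scale pretraining produces
    emb = np.maximum(encoder.encode(x), 0.0)
    emb_mean = emb.mean(axis=0)
    emb_sd = emb.std(axis=0)
    emb_sd = np.where(emb_sd > 0, emb_sd, 1.0)
    emb = (emb - emb_mean) / emb_sd
    rng = np.random.default_rng(cfg.seed)
    head = nn.mlp_init([emb.shape[1], cfg.head_hidden, 1], rng)
    opt = nn.Adam(head, lr=cfg.lr)

    def loss_at(params) -> float:
        out, _ = nn.mlp_forward(params, emb)
        loss, _ = nn.bce_with_logits(out, y, w)
        return loss

    init_loss = loss_at(head)
    n = len(y)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch):
            sel = perm[start:start + cfg.batch]
            out, cache = nn.mlp_forward(head, emb[sel])
            loss, dlogit = nn.bce_with_logits(out, y[sel], w[sel])
            if not np.isfinite(loss):
                raise TrainingError("non-finite BCE loss during fine-tuning")
            grads, _ = nn.mlp_backward(head, cache, dlogit[:, None])
            head = opt.step(head, grads)

    final_loss = loss_at(head)
    return ClassifierState(
        encoder_params=nn.params_copy(encoder.params), head_params=head,
        outcome=outcome, pretrained=encoder.pretrained, config=cfg,
        emb_mean=emb_mean, emb_sd=emb_sd,
        diagnostics={"init_loss": init_loss, "final_loss": final_loss},
    )


def train_supervised(
    x: np.ndarray,
    labels: np.ndarray,
    pre_cfg: PretrainConfig | None = None,
    cfg: FinetuneConfig | None = None,
    outcome: str = "",
) -> ClassifierState:
    """No-pretraining ablation: the same encoder+head architecture trained
    end-to-end with weighted BCE only."""
    pre_cfg = pre_cfg or PretrainConfig()
    cfg = cfg or FinetuneConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    weights = compute_class_weights(y)
    w = np.where(y > 0.5, weights[1], weights[0])
    rng = np.random.default_rng(cfg.seed)
    widths = [x.shape[1], *pre_cfg.encoder_widths, cfg.head_hidden, 1]
    params = nn.mlp_init(widths, rng)
    opt = nn.Adam(params, lr=cfg.lr)
    n = len(y)
    n_enc = len(pre_cfg.encoder_widths)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch):
            sel = perm[start:start + cfg.batch]
            out, cache = nn.mlp_forward(params, x[sel])
            loss, dlogit = nn.bce_with_logits(out, y[sel], w[sel])
            if not np.isfinite(loss):
                raise TrainingError("non-finite BCE loss during supervised training")
            grads, _ = nn.mlp_backward(params, cache, dlogit[:, None])
            params = opt.step(params, grads)
    return ClassifierState(encoder_params=params[:n_enc], head_params=params[n_enc:],
                           outcome=outcome, pretrained=False, config=cfg)


def predict_user(classifier: ClassifierState, rows: np.ndarray) -> tuple[float, bool]:
    """Average day-level probabilities into one user-level prediction."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 0:
        raise ValueError("predict_user needs at least one row")
    prob = float(np.mean(nn.sigmoid(classifier.decision_logits(rows))))
    return prob, prob >= 0.5
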