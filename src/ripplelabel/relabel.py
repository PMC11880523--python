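"""Self-supervised relabeling of noisily labeled ripple datasets.

The relabeler never reads the observed labels.  It learns a representation
of the raw 512-sample windows with two contrastive objectives in the style
of temporal/contextual contrasting frameworks for time series:

* **Temporal contrasting** — each window is augmented twice (a weak
  jitter-and-scale view and a strong permutation-and-jitter view); an
  autoregressive summarizer condenses one view's latent sequence up to a
  random timestep and linear heads predict the *other* view's future
  latents against in-batch negatives.
* **Contextual contrasting** — the two views' summary contexts are pushed
  together (same sample) and apart (different samples) with an NT-Xent
  loss over cosine similarities.

After training, every window is embedded into its context vector and
k-means with k = 2 splits the embedding cloud into groups G1/G2, which are
aligned to the observed BL/AL labels by majority vote for reporting and for
forming the intersection subset (rows where the new and old labels agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .autodiff import Tensor
from .simulate import LabeledDataset, ObservedLabel

__all__ = [
    "AugmentationConfig",
    "EncoderConfig",
    "RelabelResult",
    "weak_augment",
    "strong_augment",
    "SSLEncoder",
    "temporal_contrast_loss",
    "contextual_contrast_loss",
    "train_ssl",
    "embed",
    "relabel_kmeans",
    "align_and_compose",
    "relabel_dataset",
]

G1, G2 = 0, 1


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the weak and strong views.

    The weak view rescales the whole window and adds small jitter; the
    strong view cuts the window into a random number of contiguous
    segments, shuffles them, and adds larger jitter.
    """

    weak_scale_range: tuple[float, float] = (0.9, 1.1)
    weak_jitter_sd: float = 0.05
    strong_num_segments_range: tuple[int, int] = (4, 8)
    strong_jitter_sd: float = 0.1

    def __post_init__(self):
        lo, hi = self.strong_num_segments_range
        if lo < 1 or lo > hi:
            raise ValueError("segment counts must satisfy 1 <= lo <= hi")
        if self.weak_jitter_sd < 0 or self.strong_jitter_sd < 0:
            raise ValueError("jitter sds must be >= 0")


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and training hyperparameters of the SSL model.

    ``latent_timesteps`` is the length T of the latent sequence the encoder
    emits (512 // 32 with the default pooling); ``prediction_horizon`` K is
    how many future latent steps the temporal-contrasting heads predict
    (K < T).  ``lambda_temporal``/``lambda_contextual`` weight the two
    losses; ``temperature`` is the NT-Xent softmax temperature.
    """

    latent_dim: int = 32
    latent_timesteps: int = 16
    context_dim: int = 64
    projection_dim: int = 32
    prediction_horizon: int = 4
    temperature: float = 0.2
    lambda_temporal: float = 1.0
    lambda_contextual: float = 0.7
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 3e-4
    seed: int = 0

    def __post_init__(self):
        if self.prediction_horizon >= self.latent_timesteps:
            raise ValueError("prediction_horizon must be < latent_timesteps")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------


def weak_augment(
    x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Jitter-and-scale: multiply by a random scale and add Gaussian noise.

    Accepts a single window or a (batch, length) matrix; scales are drawn
    per window.
    """
    x = np.asarray(x, dtype=np.float32)
    batched = x.ndim == 2
    n = x.shape[0] if batched else 1
    scale = rng.uniform(*cfg.weak_scale_range, size=(n, 1)).astype(np.float32)
    noise = rng.normal(0.0, cfg.weak_jitter_sd, size=(n, x.shape[-1])).astype(
        np.float32
    ) if cfg.weak_jitter_sd > 0 else np.zeros((n, x.shape[-1]), np.float32)
    out = scale * np.atleast_2d(x) + noise
    return out if batched else out[0]


def strong_augment(
    x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Permutation-and-jitter: shuffle contiguous segments, add noise.

    With zero jitter the output is a rearrangement of the input samples
    (the sample multiset is conserved).
    """
    x = np.asarray(x, dtype=np.float32)
    batched = x.ndim == 2
    rows = np.atleast_2d(x)
    length = rows.shape[1]
    lo, hi = cfg.strong_num_segments_range
    if hi > length:
        raise ValueError("more segments than samples")
    out = np.empty_like(rows)
    for i, row in enumerate(rows):
        m = int(rng.integers(lo, hi + 1))
        if m == 1:
            out[i] = row
            continue
        cuts = np.sort(rng.choice(np.arange(1, length), size=m - 1, replace=False))
        segments = np.split(row, cuts)
        order = rng.permutation(m)
        out[i] = np.concatenate([segments[j] for j in order])
    if cfg.strong_jitter_sd > 0:
        out = out + rng.normal(0.0, cfg.strong_jitter_sd, out.shape).astype(np.float32)
    return out if batched else out[0]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class SSLEncoder(nn.Module):
    """Convolutional encoder + autoregressive summarizer + heads."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.latent_dim
        self.conv = nn.Sequential(
            nn.Conv1d(1, 16, 7, rng), nn.BatchNorm1d(16), nn.ReLU(), nn.MaxPool1d(4),
            nn.Conv1d(16, 32, 5, rng), nn.BatchNorm1d(32), nn.ReLU(), nn.MaxPool1d(4),
            nn.Conv1d(32, d, 3, rng), nn.BatchNorm1d(d), nn.ReLU(), nn.MaxPool1d(2),
        )
        self.ar = nn.GRU(d, cfg.context_dim, rng)
        self.predict_heads = [
            nn.Linear(cfg.context_dim, d, rng) for _ in range(cfg.prediction_horizon)
        ]
        self.project = nn.Sequential(
            nn.Linear(cfg.context_dim, cfg.context_dim, rng),
            nn.ReLU(),
            nn.Linear(cfg.context_dim, cfg.projection_dim, rng),
        )

    def encode(self, x: np.ndarray | Tensor) -> Tensor:
        """Map (N, 512) windows to latent sequences (N, T, latent_dim)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 2:
            raise ValueError("expected a (batch, length) matrix")
        n, length = x.shape
        z = self.conv(x.reshape(n, length, 1))  # (N, T, D)
        if z.shape[1] != self.cfg.latent_timesteps:
            raise ValueError(
                f"input length {length} yields {z.shape[1]} latent steps, "
                f"configured {self.cfg.latent_timesteps}"
            )
        return z

    def context(self, latents: Tensor) -> Tensor:
        """Autoregressive summary (N, context_dim) of a latent sequence."""
        return self.ar(latents)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def temporal_contrast_loss(
    model: SSLEncoder,
    strong_latents: Tensor,
    weak_latents: Tensor,
    t: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Cross-view future-prediction loss against in-batch negatives.

    The summarizer condenses one view's latents up to timestep ``t``
    (uniformly drawn if not given); for every horizon k = 1..K a linear
    head predicts the other view's latent at t+k, scored against all other
    samples' latents at that step by dot product and penalized with softmax
    cross-entropy.  Both directions (strong->weak, weak->strong) are
    averaged.
    """
    _, big_t, _ = strong_latents.shape
    k_max = model.cfg.prediction_horizon
    if k_max >= big_t:
        raise ValueError("prediction horizon must be below the latent length")
    if t is None:
        t = int((rng or np.random.default_rng()).integers(0, big_t - k_max))
    states_s = model.ar(strong_latents, return_sequence=True)
    states_w = model.ar(weak_latents, return_sequence=True)
    return _temporal_loss_from_states(
        model, states_s, states_w, strong_latents, weak_latents, t
    )


def _temporal_loss_from_states(
    model: SSLEncoder,
    states_strong: list[Tensor],
    states_weak: list[Tensor],
    strong_latents: Tensor,
    weak_latents: Tensor,
    t: int,
) -> Tensor:
    """Both directions of the future-prediction loss from GRU state lists.

    ``states[t]`` is the causal context of the sequence up to t, so reusing
    one full GRU pass per view is exactly the context of a truncated pass.
    """
    k_max = model.cfg.prediction_horizon
    n = strong_latents.shape[0]
    targets = np.arange(n)
    total = None
    for states, future_latents in (
        (states_strong, weak_latents),
        (states_weak, strong_latents),
    ):
        c = states[t]
        for k in range(1, k_max + 1):
            pred = model.predict_heads[k - 1](c)  # (N, D)
            z_k = future_latents[:, t + k, :]  # (N, D)
            scores = pred @ z_k.transpose(1, 0)  # (N, N)
            term = nn.softmax_cross_entropy(scores, targets)
            total = term if total is None else total + term
    return total * (1.0 / (2 * k_max))


def contextual_contrast_loss(proj_a: Tensor, proj_b: Tensor, temperature: float) -> Tensor:
    """NT-Xent loss over the two views' projected contexts.

    Each of the 2N projections is an anchor; its positive is the sibling
    view of the same sample, its negatives the remaining 2N - 2
    projections.  Similarity is cosine, scaled by ``temperature``.
    """
    n = proj_a.shape[0]
    if n < 2:
        raise ValueError("contextual contrasting needs at least 2 samples")
    from .autodiff import concatenate

    z = concatenate([proj_a, proj_b], axis=0)  # (2N, P)
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    z = z / norm
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)  # (2N, 2N)
    # mask self-similarity out of the softmax denominator
    mask = Tensor(np.where(np.eye(2 * n, dtype=bool), -1e9, 0.0).astype(np.float32))
    sim = sim + mask
    targets = np.r_[np.arange(n, 2 * n), np.arange(n)]
    return nn.softmax_cross_entropy(sim, targets)


# ---------------------------------------------------------------------------
# training / embedding / clustering
# ---------------------------------------------------------------------------


def train_ssl(
    dataset: LabeledDataset | np.ndarray,
    cfg: EncoderConfig = EncoderConfig(),
    aug: AugmentationConfig = AugmentationConfig(),
    progress: bool = False,
) -> tuple[SSLEncoder, list[float]]:
    """Train the SSL model on raw windows; labels are never consumed.

    Returns the trained encoder and the per-epoch mean loss history.  The
    run is a pure function of (signals, cfg, aug) through ``cfg.seed``.
    """
    signals = dataset.signals if isinstance(dataset, LabeledDataset) else dataset
    signals = np.asarray(signals, dtype=np.float32)
    n = len(signals)
    if n == 0:
        raise ValueError("empty dataset")
    if cfg.batch_size > n:
        raise ValueError("batch_size exceeds the dataset size")
    rng = np.random.default_rng(cfg.seed)
    model = SSLEncoder(cfg, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = signals[order[start : start + cfg.batch_size]]
            strong = strong_augment(batch, aug, rng)
            weak = weak_augment(batch, aug, rng)
            z_s = model.encode(strong)
            z_w = model.encode(weak)
            t = int(rng.integers(0, cfg.latent_timesteps - cfg.prediction_horizon))
            states_s = model.ar(z_s, return_sequence=True)
            states_w = model.ar(z_w, return_sequence=True)
            lt = _temporal_loss_from_states(model, states_s, states_w, z_s, z_w, t)
            proj_s = model.project(states_s[-1])
            proj_w = model.project(states_w[-1])
            lc = contextual_contrast_loss(proj_s, proj_w, cfg.temperature)
            loss = cfg.lambda_temporal * lt + cfg.lambda_contextual * lc
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if progress:  # pragma: no cover - console feedback only
            print(f"ssl epoch {epoch + 1}/{cfg.epochs}  loss {history[-1]:.4f}")
    return model, history


def embed(
    model: SSLEncoder,
    dataset: LabeledDataset | np.ndarray,
    batch_size: int = 256,
    space: str = "latent_mean",
) -> np.ndarray:
    """One embedding vector per window, evaluation mode, no augmentation.

    ``space`` selects the representation: ``"latent_mean"`` (default) is
    the encoder's latent sequence averaged over time, which is stable
    across training stages because it sits directly on the convolutional
    features; ``"context"`` is the autoregressive summary vector that the
    contextual-contrasting head trains on.
    """
    if space not in ("latent_mean", "context"):
        raise ValueError(f"unknown embedding space {space!r}")
    signals = dataset.signals if isinstance(dataset, LabeledDataset) else dataset
    signals = np.asarray(signals, dtype=np.float32)
    model.eval()
    chunks = []
    for start in range(0, len(signals), batch_size):
        z = model.encode(signals[start : start + batch_size])
        if space == "context":
            chunks.append(model.context(z).numpy())
        else:
            chunks.append(z.numpy().mean(axis=1))
    model.train()
    return np.concatenate(chunks, axis=0)


def relabel_kmeans(
    embeddings: np.ndarray,
    seed: int = 0,
    whiten_components: int | None = 8,
) -> np.ndarray:
    """Split the embedding cloud into two groups with restarted k-means.

    By default the embeddings are first projected onto their leading
    ``whiten_components`` principal components and whitened, so the
    partition is driven by the dominant shape of the cloud rather than by
    whichever raw feature carries the largest variance, and the many
    near-noise embedding directions cannot swamp the cluster distance.
    Pass ``whiten_components=None`` to cluster the raw embeddings.
    """
    embeddings = np.asarray(embeddings)
    if len(embeddings) < 2:
        raise ValueError("need at least 2 rows to form 2 clusters")
    if whiten_components is not None:
        from sklearn.decomposition import PCA

        n_comp = min(whiten_components, embeddings.shape[1], len(embeddings) - 1)
        embeddings = PCA(
            n_components=n_comp, whiten=True, random_state=seed
        ).fit_transform(embeddings)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(embeddings).astype(np.int64)


@dataclass
class RelabelResult:
    """Aligned SSL groups, their composition, and the intersection mask.

    ``group`` holds G1/G2 codes after alignment (G1 = the cluster holding
    the majority of BL rows).  ``composition`` is the 2x2 count table with
    groups on rows and observed labels on columns.  ``intersection_mask``
    marks rows whose group agrees with their observed label (G1 & BL or
    G2 & AL).
    """

    group: np.ndarray
    alignment: dict[int, int] = field(default_factory=dict)
    composition: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), int))
    intersection_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def composition_within_group(self) -> np.ndarray:
        """Row-normalized composition: share of BL/AL inside each group."""
        return self.composition / self.composition.sum(axis=1, keepdims=True)

    @property
    def composition_within_label(self) -> np.ndarray:
        """Column-normalized composition: share of each label caught per group."""
        return self.composition / self.composition.sum(axis=0, keepdims=True)


def align_and_compose(group: np.ndarray, observed: np.ndarray) -> RelabelResult:
    """Name the clusters G1/G2 by majority vote against the observed labels.

    The cluster holding the larger share of BL rows becomes G1 (ties keep
    cluster index order).  Classifier training on the group labels is
    invariant to this naming; it only fixes the reporting convention and
    the intersection subset.
    """
    group = np.asarray(group)
    observed = np.asarray(observed)
    if group.shape != observed.shape:
        raise ValueError("group and observed labels must align")
    bl = observed == ObservedLabel.BL
    bl_in_0 = int(np.sum(bl & (group == 0)))
    bl_in_1 = int(np.sum(bl & (group == 1)))
    if bl_in_1 > bl_in_0:
        alignment = {0: G2, 1: G1}
    else:
        alignment = {0: G1, 1: G2}
    aligned = np.where(group == 0, alignment[0], alignment[1]).astype(np.int64)
    composition = np.zeros((2, 2), dtype=np.int64)
    for g in (G1, G2):
        for lab in (ObservedLabel.BL, ObservedLabel.AL):
            composition[g, int(lab)] = int(np.sum((aligned == g) & (observed == lab)))
    mask = ((aligned == G1) & (observed == ObservedLabel.BL)) | (
        (aligned == G2) & (observed == ObservedLabel.AL)
    )
    return RelabelResult(aligned, alignment, composition, mask)


def relabel_dataset(
    dataset: LabeledDataset,
    cfg: EncoderConfig = EncoderConfig(),
    aug: AugmentationConfig = AugmentationConfig(),
    progress: bool = False,
) -> tuple[RelabelResult, np.ndarray, SSLEncoder]:
    """End-to-end relabeling: train SSL, embed, cluster, align.

    Returns the relabel result, the embedding matrix, and the trained
    encoder.
    """
    model, _ = train_ssl(dataset, cfg, aug, progress=progress)
    emb = embed(model, dataset)
    group = relabel_kmeans(emb, seed=cfg.seed)
    return align_and_compose(group, dataset.observed_label), emb, model
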