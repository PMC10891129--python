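"""Synthetic inputs for the whole pipeline.

Two kinds of data are produced here:

1. Regression datasets drawn from four benchmark target functions
   (a noisy line, a saturating exponential, a noisy quadratic and the
   Forrester function), the raw material for the optimizer-conformance
   study.
2. Raster images of random network drawings, emulating a corpus of
   single-cell gene-regulatory-network (SCGRN) visualisations with a
   balanced healthy / T2D class split, plus a multi-class variant used
   as a source task for transfer-learning experiments.

Everything is deterministic under an integer seed: regenerating with the
same settings reproduces arrays bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = [
    "TARGET_FUNCTION_IDS",
    "RegressionDataset",
    "NetworkImageCorpus",
    "eval_target_function",
    "generate_regression_data",
    "generate_network_image_corpus",
    "make_source_task_corpus",
    "default_binary_class_params",
    "class_edge_stats",
    "save_corpus",
    "load_corpus",
]

TARGET_FUNCTION_IDS = ("F1", "F2", "F3", "F4")

#: Binary corpus class order: index 0 = disease, index 1 = healthy, so a
#: softmax "healthy" score is always channel 1 downstream.
BINARY_CLASS_NAMES = ("T2D", "healthy")


# ---------------------------------------------------------------------------
# Regression side
# ---------------------------------------------------------------------------

def eval_target_function(fn_id: str, x):
    """Noise-free value of one of the four benchmark target functions.

    F1(x) = 0.5 + 0.79 x                 (linear)
    F2(x) = 1 - exp(-1 / (2x)),  x > 0   (saturating; undefined at x <= 0)
    F3(x) = 0.7 + 3 x^2                  (quadratic)
    F4(x) = (6x - 2)^2 + sin(12x - 4)    (Forrester benchmark)

    ``x`` may be a scalar or an array; the return matches its shape.
    """
    xa = np.asarray(x, dtype=float)
    if fn_id == "F1":
        out = 0.5 + 0.79 * xa
    elif fn_id == "F2":
        if np.any(xa <= 0.0):
            raise ValueError("F2 requires x > 0 (its exponent is -1/(2x))")
        out = 1.0 - np.exp(-1.0 / (2.0 * xa))
    elif fn_id == "F3":
        out = 0.7 + 3.0 * xa ** 2
    elif fn_id == "F4":
        out = (6.0 * xa - 2.0) ** 2 + np.sin(12.0 * xa - 4.0)
    else:
        raise ValueError(f"unknown target function id {fn_id!r}; expected one of {TARGET_FUNCTION_IDS}")
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


#: Functions whose generative definition carries an additive noise term.
NOISY_FUNCTIONS = frozenset({"F1", "F3"})


@dataclass(frozen=True)
class RegressionDataset:
    """An (x, y) sample from one benchmark function with its noise model."""

    fn_id: str
    x: np.ndarray
    y: np.ndarray
    m: int
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.fn_id not in TARGET_FUNCTION_IDS:
            raise ValueError(f"unknown fn_id {self.fn_id!r}")
        if self.m < 2:
            raise ValueError("a regression dataset needs m >= 2 samples")
        if len(self.x) != self.m or len(self.y) != self.m:
            raise ValueError("x and y must both have length m")
        if np.any(self.x <= 0.0) or np.any(self.x >= 1.0):
            raise ValueError("x must lie strictly inside (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_regression_data(
    fn_id: str, m: int = 100, seed: int = 0, noise_sd: float = 0.2
) -> RegressionDataset:
    """Draw ``m`` points with x ~ U(0,1) and y from the chosen function.

    Gaussian noise N(0, noise_sd) is added only for F1 and F3, whose
    generative definitions include an additive error term; F2 and F4 are
    deterministic curves. x is kept strictly inside the open interval
    (0, 1) so that F2's domain is always respected.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=m)
    # uniform() covers [0, 1); redraw the measure-zero endpoints so the
    # open-interval invariant holds exactly.
    bad = (x <= 0.0) | (x >= 1.0)
    while np.any(bad):
        x[bad] = rng.uniform(size=int(bad.sum()))
        bad = (x <= 0.0) | (x >= 1.0)
    y = eval_target_function(fn_id, x)
    if fn_id in NOISY_FUNCTIONS and noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=m)
    return RegressionDataset(fn_id=fn_id, x=x, y=np.asarray(y, dtype=float), m=m, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# Image-corpus side
# ---------------------------------------------------------------------------

@dataclass
class NetworkImageCorpus:
    """Labelled raster images of synthetic network drawings.

    ``images`` is an (N, H, W, 3) float32 array with values in [0, 1]
    (white background, dark edges and nodes; one grey channel replicated
    three times). ``labels`` holds one class name per image.
    """

    images: np.ndarray
    labels: list[str]
    class_names: tuple[str, ...]
    class_params: Mapping[str, Mapping]
    image_size: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_indices(self) -> np.ndarray:
        lut = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lut[lab] for lab in self.labels], dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        return {name: self.labels.count(name) for name in self.class_names}


def default_binary_class_params(edge_margin: int = 20) -> dict[str, dict]:
    """Per-class graph-generator settings for the healthy/T2D corpus.

    Both classes draw preferential-attachment (Barabási–Albert) graphs;
    they differ in the attachment parameter, i.e. how many edges each new
    node brings. The disease class is denser and more hub-dominated, the
    healthy class sparser — a controllable structural gap whose expected
    edge-count difference is well above ``edge_margin`` at the default
    node counts.
    """
    return {
        "T2D": {"kind": "ba", "attachment": 4, "n_nodes": (25, 40)},
        "healthy": {"kind": "ba", "attachment": 2, "n_nodes": (25, 40)},
        "edge_margin": edge_margin,
    }


def _sample_graph(params: Mapping, rng: np.random.Generator) -> nx.Graph:
    lo, hi = params.get("n_nodes", (25, 40))
    n = int(rng.integers(lo, hi + 1))
    gseed = int(rng.integers(0, 2**31 - 1))
    kind = params.get("kind", "ba")
    if kind == "ba":
        m_attach = int(params.get("attachment", 2))
        m_attach = min(m_attach, n - 1)
        return nx.barabasi_albert_graph(n, m_attach, seed=gseed)
    if kind == "er":
        p = float(params.get("p", 0.15))
        return nx.gnp_random_graph(n, p, seed=gseed)
    if kind == "ws":
        k = int(params.get("k", 4))
        p = float(params.get("p", 0.1))
        return nx.watts_strogatz_graph(n, min(k, n - 1), p, seed=gseed)
    raise ValueError(f"unknown graph kind {kind!r}")


_SUPERSAMPLE = 4  # draw at 4x resolution, then downscale for anti-aliasing


def _render_graph(graph: nx.Graph, image_size: int, layout_seed: int) -> np.ndarray:
    """Rasterise a graph drawing onto a white canvas, values in [0, 1]."""
    pos = nx.spring_layout(graph, seed=layout_seed)
    big = image_size * _SUPERSAMPLE
    pad = 0.08 * big
    coords = np.array([pos[v] for v in graph.nodes()], dtype=float)
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span == 0] = 1.0
    scaled = (coords - coords.min(axis=0)) / span
    pix = pad + scaled * (big - 2 * pad)
    xy = {v: (float(pix[i, 0]), float(pix[i, 1])) for i, v in enumerate(graph.nodes())}

    img = Image.new("L", (big, big), color=255)
    draw = ImageDraw.Draw(img)
    lw = max(1, _SUPERSAMPLE // 2)
    for u, v in graph.edges():
        draw.line([xy[u], xy[v]], fill=70, width=lw)
    r = 1.5 * _SUPERSAMPLE
    for v in graph.nodes():
        cx, cy = xy[v]
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=0)
    small = img.resize((image_size, image_size), Image.LANCZOS)
    grey = np.asarray(small, dtype=np.float32) / 255.0
    return np.repeat(grey[:, :, None], 3, axis=2)


def generate_network_image_corpus(
    n_images: int = 224,
    image_size: int = 64,
    class_params: Mapping | None = None,
    seed: int = 0,
    balanced: bool = True,
) -> NetworkImageCorpus:
    """Generate the two-class (T2D vs healthy) network-image corpus.

    With ``balanced=True`` (the default, matching the real corpus this
    emulates) the ``n_images`` drawings are split evenly between the two
    classes, e.g. 224 -> 112 T2D + 112 healthy.
    """
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    if balanced and n_images % 2 != 0:
        raise ValueError("balanced generation needs an even n_images")
    params = dict(class_params) if class_params is not None else default_binary_class_params()

    per_class = n_images // 2
    labels = [BINARY_CLASS_NAMES[0]] * per_class + [BINARY_CLASS_NAMES[1]] * (n_images - per_class)
    ss = np.random.SeedSequence(seed)
    images = np.empty((n_images, image_size, image_size, 3), dtype=np.float32)
    for i, (label, child) in enumerate(zip(labels, ss.spawn(n_images))):
        rng = np.random.default_rng(child)
        graph = _sample_graph(params[label], rng)
        layout_seed = int(rng.integers(0, 2**31 - 1))
        images[i] = _render_graph(graph, image_size, layout_seed)
    return NetworkImageCorpus(
        images=images,
        labels=labels,
        class_names=BINARY_CLASS_NAMES,
        class_params=params,
        image_size=image_size,
        seed=seed,
    )


def make_source_task_corpus(
    n_images: int = 240,
    n_classes: int = 4,
    image_size: int = 64,
    seed: int = 0,
) -> NetworkImageCorpus:
    """Multi-class corpus of structurally distinct network drawings.

    Serves as the source task for pretraining the convolutional base (a
    desk-scale stand-in for large natural-image pretraining). Classes
    cycle through different generators — trees, dense preferential
    attachment, Erdős–Rényi, small-world — so their drawings differ in
    edge density and geometry.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    archetypes = [
        {"kind": "ba", "attachment": 1, "n_nodes": (25, 40)},
        {"kind": "ba", "attachment": 4, "n_nodes": (25, 40)},
        {"kind": "er", "p": 0.25, "n_nodes": (25, 40)},
        {"kind": "ws", "k": 4, "p": 0.05, "n_nodes": (25, 40)},
        {"kind": "ba", "attachment": 2, "n_nodes": (25, 40)},
        {"kind": "er", "p": 0.08, "n_nodes": (25, 40)},
    ]
    class_names = tuple(f"src{k}" for k in range(n_classes))
    params = {name: archetypes[k % len(archetypes)] for k, name in enumerate(class_names)}

    base, extra = divmod(n_images, n_classes)
    counts = [base + (1 if k < extra else 0) for k in range(n_classes)]
    labels = [name for name, c in zip(class_names, counts) for _ in range(c)]
    ss = np.random.SeedSequence(seed)
    images = np.empty((n_images, image_size, image_size, 3), dtype=np.float32)
    for i, (label, child) in enumerate(zip(labels, ss.spawn(n_images))):
        rng = np.random.default_rng(child)
        graph = _sample_graph(params[label], rng)
        layout_seed = int(rng.integers(0, 2**31 - 1))
        images[i] = _render_graph(graph, image_size, layout_seed)
    return NetworkImageCorpus(
        images=images,
        labels=labels,
        class_names=class_names,
        class_params=params,
        image_size=image_size,
        seed=seed,
    )


def class_edge_stats(
    class_params: Mapping[str, Mapping], n_samples: int = 50, seed: int = 0
) -> dict[str, float]:
    """Mean graph edge count per class under the given generator settings.

    A classifier-free separability check: the configured structural gap
    between classes should show up directly in this statistic.
    """
    out: dict[str, float] = {}
    ss = np.random.SeedSequence(seed)
    for name, params in class_params.items():
        if not isinstance(params, Mapping):
            continue  # scalar settings like edge_margin
        rng = np.random.default_rng(ss.spawn(1)[0])
        out[name] = float(
            np.mean([_sample_graph(params, rng).number_of_edges() for _ in range(n_samples)])
        )
    return out


# ---------------------------------------------------------------------------
# Corpus persistence: PNG files plus a CSV manifest
# ---------------------------------------------------------------------------

def save_corpus(corpus: NetworkImageCorpus, out_dir) -> pd.DataFrame:
    """Write the corpus as PNG files plus a ``manifest.csv`` (filename,label)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ndigits = max(4, len(str(len(corpus))))
    rows = []
    for i, label in enumerate(corpus.labels):
        fname = f"img_{i:0{ndigits}d}_{label}.png"
        arr = np.clip(corpus.images[i] * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / fname)
        rows.append({"filename": fname, "label": label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_corpus(in_dir, class_names: Sequence[str] | None = None) -> NetworkImageCorpus:
    """Read a corpus back from the PNG + manifest layout of :func:`save_corpus`."""
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    labels = [str(lab) for lab in manifest["label"]]
    if class_names is None:
        if set(labels) == set(BINARY_CLASS_NAMES):
            class_names = BINARY_CLASS_NAMES
        else:
            class_names = tuple(sorted(set(labels)))
    imgs = []
    for fname in manifest["filename"]:
        with Image.open(root / fname) as im:
            imgs.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    images = np.stack(imgs)
    return NetworkImageCorpus(
        images=images,
        labels=labels,
        class_names=tuple(class_names),
        class_params={},
        image_size=images.shape[1],
        seed=-1,
    )
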