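"""Synthetic mammogram-like phantoms and simulated classifier outputs.

The phantom generator stands in for a mammographic mass database so the whole
pipeline runs offline.  It reproduces the two margin phenotypes that drive
mass classification: benign masses as bright discs with smooth, blurred
margins; malignant masses as discs with sharp margins plus radial spicules
("needle-like" extensions).  "Ignorant" (normal) phantoms contain background
tissue texture only.  Salt-and-pepper and Gaussian noise are applied last,
emulating film digitization artifacts.

``simulate_source_pair`` emulates the *outputs* of two trained classifiers —
per-sample probability triples over (benign, malignant, ignorant) — with
controllable marginal accuracy and inter-source error correlation.  It is the
ground-truth harness for studying decision-level fusion in isolation from any
particular classifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image import GrayImage, write_image

__all__ = [
    "CLASSES",
    "PhantomSpec",
    "SimulatedSourceSpec",
    "PhantomDataset",
    "generate_phantom",
    "generate_phantom_dataset",
    "simulate_source_pair",
    "write_dataset",
    "write_sources_csv",
    "read_sources_csv",
]

#: Fixed class order used everywhere in the package (one-hot, masses, CSVs).
CLASSES: tuple[str, str, str] = ("benign", "malignant", "ignorant")

# Intensity layout of a phantom (8-bit scale): mid-gray tissue background
# with a brighter mass.  Chosen so Otsu binarization separates mass pixels
# and noise never saturates the whole frame.
_BG_MEAN = 90.0
_BG_AMPLITUDE = 22.0
_MASS_AMPLITUDE = 75.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom image.

    Parameters
    ----------
    image_size : int
        Pixels per side (square image), >= 32.
    class_label : str
        One of ``benign``, ``malignant``, ``ignorant``.
    mass_radius : float
        Mass radius in pixels (ignored for ``ignorant``).
    spicule_count : int
        Number of radial spicules; >= 4 for malignant, 0 otherwise.
    noise_salt_pepper_frac : float
        Fraction of pixels replaced by 0 or L-1 impulses, in [0, 1].
    noise_gaussian_sigma : float
        Std-dev of additive Gaussian noise, in intensity units.
    background_texture_scale : float
        Correlation length (pixels) of the smoothed background texture.
    seed : int
        RNG seed; the generator is a pure function of the spec.
    """

    image_size: int = 128
    class_label: str = "benign"
    mass_radius: float = 14.0
    spicule_count: int = 8
    noise_salt_pepper_frac: float = 0.01
    noise_gaussian_sigma: float = 4.0
    background_texture_scale: float = 8.0
    seed: int = 0
    levels: int = 256

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ParameterError(f"image_size must be >= 32, got {self.image_size}")
        if self.class_label not in CLASSES:
            raise ParameterError(f"class_label must be one of {CLASSES}")
        if not 0.0 <= self.noise_salt_pepper_frac <= 1.0:
            raise ParameterError("noise_salt_pepper_frac must be in [0, 1]")
        if self.noise_gaussian_sigma < 0:
            raise ParameterError("noise_gaussian_sigma must be >= 0")
        if self.mass_radius <= 0:
            raise ParameterError("mass_radius must be positive")
        if self.class_label == "malignant" and self.spicule_count < 4:
            raise ParameterError("malignant phantoms need spicule_count >= 4")


@dataclass(frozen=True)
class SimulatedSourceSpec:
    """Parameters for a pair of simulated probability sources.

    ``error_correlation`` couples the two sources' error *events*: 0 means
    independent mistakes, 1 means comonotone mistakes (with equal accuracies,
    the sources err on exactly the same samples).
    ``confidence_concentration`` is the Dirichlet concentration placed on the
    predicted class; erroneous predictions use a quarter of it, reflecting
    that classifier posteriors are typically less peaked on mistakes.
    """

    n_samples: int
    accuracy_source1: float = 0.92
    accuracy_source2: float = 0.95
    error_correlation: float = 0.0
    confidence_concentration: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        for acc in (self.accuracy_source1, self.accuracy_source2):
            if not 0.0 < acc <= 1.0:
                raise ParameterError(f"accuracies must be in (0, 1], got {acc}")
        if not 0.0 <= self.error_correlation <= 1.0:
            raise ParameterError("error_correlation must be in [0, 1]")
        if self.confidence_concentration <= 0:
            raise ParameterError("confidence_concentration must be positive")


@dataclass
class PhantomDataset:
    """A labelled collection of phantom images."""

    images: list[GrayImage]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.images)


def _background(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Smoothed uniform noise: tissue-like texture with correlation length ~scale."""
    noise = rng.random((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=max(scale / 2.0, 0.5), mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.full((size, size), _BG_MEAN)
    return _BG_MEAN + _BG_AMPLITUDE * (smooth - smooth.mean()) / sd


def _disc(size: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2).astype(float)


def _spicules(
    size: int,
    cx: float,
    cy: float,
    radius: float,
    count: int,
    rng: np.random.Generator,
    width: float = 1.6,
) -> np.ndarray:
    """Radial needle-like segments from 0.6*r to 1.5*r around the mass."""
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    out = np.zeros((size, size))
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(count):
        theta = phase + 2 * np.pi * k / count + rng.normal(0, 0.08)
        ux, uy = np.cos(theta), np.sin(theta)
        along = dx * ux + dy * uy          # signed distance along the spicule axis
        across = np.abs(-dx * uy + dy * ux)  # perpendicular distance to the axis
        seg = (along >= 0.6 * radius) & (along <= 1.5 * radius) & (across <= width / 2)
        out[seg] = 1.0
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, str]:
    """Generate one phantom image; deterministic given the spec (incl. seed).

    Returns the 8-bit image and its class label.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(rng, size, spec.background_texture_scale)

    if spec.class_label != "ignorant":
        # mass position jittered around the center, radius jittered +-15%,
        # so a dataset of phantoms is not a set of translated copies
        cx = size / 2 + rng.uniform(-size / 8, size / 8)
        cy = size / 2 + rng.uniform(-size / 8, size / 8)
        radius = spec.mass_radius * rng.uniform(0.85, 1.15)
        mass = _disc(size, cx, cy, radius)
        if spec.class_label == "benign":
            # smooth, uniform margin: heavy blur of the disc edge
            mass = ndimage.gaussian_filter(mass, sigma=radius / 4.0, mode="constant")
        else:
            mass = np.maximum(
                mass, _spicules(size, cx, cy, radius, spec.spicule_count, rng)
            )
            # sub-pixel softening only; the margin stays sharp
            mass = ndimage.gaussian_filter(mass, sigma=0.5, mode="constant")
        img = img + _MASS_AMPLITUDE * mass

    # noise last: additive Gaussian, then salt-and-pepper impulses
    if spec.noise_gaussian_sigma > 0:
        img = img + rng.normal(0, spec.noise_gaussian_sigma, img.shape)
    img = np.clip(np.floor(img + 0.5), 0, spec.levels - 1)
    if spec.noise_salt_pepper_frac > 0:
        impulse = rng.random(img.shape) < spec.noise_salt_pepper_frac
        salt = rng.random(img.shape) < 0.5
        img = np.where(impulse, np.where(salt, spec.levels - 1, 0), img)
    return GrayImage(img.astype(np.int64), levels=spec.levels), spec.class_label


def generate_phantom_dataset(
    n_per_class: int, spec_template: PhantomSpec, seed: int
) -> PhantomDataset:
    """Balanced dataset: ``n_per_class`` phantoms per class, seeded reproducibly.

    Per-image seeds are spawned from the master seed with
    :class:`numpy.random.SeedSequence`, so the collection is a pure function
    of ``(n_per_class, spec_template, seed)`` and images are mutually
    independent.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * n_per_class)]
    images: list[GrayImage] = []
    labels: list[str] = []
    i = 0
    for cls in CLASSES:
        for _ in range(n_per_class):
            spec = replace(
                spec_template,
                class_label=cls,
                spicule_count=spec_template.spicule_count if cls == "malignant" else 0,
                seed=child_seeds[i],
            )
            if cls == "malignant" and spec.spicule_count < 4:
                spec = replace(spec, spicule_count=8)
            img, lab = generate_phantom(spec)
            images.append(img)
            labels.append(lab)
            i += 1
    return PhantomDataset(images=images, labels=labels)


def _dirichlet_peaked(
    rng: np.random.Generator, chosen: np.ndarray, concentration: np.ndarray
) -> np.ndarray:
    """Draw (n, 3) probability triples peaked on ``chosen`` (argmax guaranteed).

    Gamma-based Dirichlet draw with per-sample concentration on the chosen
    class; the largest component is then swapped into the chosen slot so the
    triple's argmax always equals the simulated prediction.
    """
    n = chosen.shape[0]
    alpha = np.ones((n, 3))
    alpha[np.arange(n), chosen] = concentration
    g = rng.gamma(shape=alpha)
    p = g / g.sum(axis=1, keepdims=True)
    idx_max = np.argmax(p, axis=1)
    rows = np.arange(n)
    pmax = p[rows, idx_max].copy()
    pcho = p[rows, chosen].copy()
    p[rows, idx_max] = pcho
    p[rows, chosen] = pmax
    return p


def simulate_source_pair(
    spec: SimulatedSourceSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate aligned probability outputs of two classifiers.

    Returns
    -------
    (labels, probs1, probs2)
        ``labels`` — array of n true class names; ``probs{1,2}`` — (n, 3)
        arrays of probability triples in :data:`CLASSES` order, each row
        summing to 1, whose argmax equals the simulated prediction.

    Notes
    -----
    Error events are coupled through a shared uniform variate: source *i*
    errs iff ``u_i < 1 - accuracy_i``, with ``u_2`` equal to ``u_1`` with
    probability ``error_correlation`` and fresh otherwise.  An erroneous
    prediction picks one of the two wrong classes uniformly and its triple
    is drawn with a quarter of the confidence concentration.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    true = rng.integers(0, 3, size=n)

    u1 = rng.random(n)
    u2 = np.where(rng.random(n) < spec.error_correlation, u1, rng.random(n))
    err1 = u1 < (1.0 - spec.accuracy_source1)
    err2 = u2 < (1.0 - spec.accuracy_source2)

    wrong_offset1 = rng.integers(1, 3, size=n)
    wrong_offset2 = rng.integers(1, 3, size=n)
    pred1 = np.where(err1, (true + wrong_offset1) % 3, true)
    pred2 = np.where(err2, (true + wrong_offset2) % 3, true)

    c = spec.confidence_concentration
    conc1 = np.where(err1, c / 4.0, c)
    conc2 = np.where(err2, c / 4.0, c)
    probs1 = _dirichlet_peaked(rng, pred1, conc1)
    probs2 = _dirichlet_peaked(rng, pred2, conc2)

    labels = np.array([CLASSES[t] for t in true])
    return labels, probs1, probs2


def write_dataset(dataset: PhantomDataset, out_dir: str | Path, fmt: str = "pgm") -> Path:
    """Write phantom images plus a ``labels.csv`` (columns: filename, label)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        name = f"phantom_{i:04d}.{fmt}"
        write_image(img, out_dir / name)
        rows.append((name, lab))
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return out_dir


def write_sources_csv(
    path: str | Path, labels: np.ndarray, probs1: np.ndarray, probs2: np.ndarray
) -> None:
    """Write aligned two-source probabilities in the fusion CSV layout."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "true_label"]
            + [f"p1_{c}" for c in CLASSES]
            + [f"p2_{c}" for c in CLASSES]
        )
        for i, (lab, p1, p2) in enumerate(zip(labels, probs1, probs2)):
            w.writerow([i, lab] + [f"{v:.9f}" for v in p1] + [f"{v:.9f}" for v in p2])


def read_sources_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_sources_csv`."""
    labels, p1s, p2s = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels.append(row["true_label"])
            p1s.append([float(row[f"p1_{c}"]) for c in CLASSES])
            p2s.append([float(row[f"p2_{c}"]) for c in CLASSES])
    return np.array(labels), np.array(p1s), np.array(p2s)
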