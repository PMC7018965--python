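"""Synthetic two-class feature matrices and toy cell images with known planted structure.

The generator emulates the setting of rectified CNN bottleneck features for a
benign/malignant cell classification problem: a handful of *informative*
columns whose class-conditional means differ, *redundant* columns that are
noisy linear copies of informative ones, and label-independent *noise*
columns.  Knowing exactly which columns carry signal lets every downstream
stage (filters, swarm search, evaluation) be tested without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_feature_dataset",
    "make_toy_cell_images",
    "save_dataset",
    "load_dataset",
    "save_toy_images",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-structure two-class feature matrix.

    Parameters
    ----------
    n_samples : int
        Number of rows (cells/images emulated).
    n_informative : int
        Columns whose class-conditional means are separated by
        ``effect_size`` standard deviations (per-class means at
        ``±effect_size/2``, unit sd).
    n_redundant : int
        Columns of the form ``a * source + noise`` where ``source`` is a
        randomly chosen informative column, ``a ~ U[0.5, 1.5]`` and the
        noise is Gaussian with sd ``redundancy_noise_sd``.
    n_noise : int
        Standard-normal columns independent of the labels.
    effect_size : float
        Between-class mean shift of informative columns, in units of their
        (unit) standard deviation.
    redundancy_noise_sd : float
        Standard deviation of the additive noise on redundant columns.
    class_balance : float
        Fraction of samples in class 1 (malignant); must lie in (0, 1).
    nonnegative : bool
        If true, all values are rectified at 0 as the final step, mimicking
        post-ReLU CNN activations (and satisfying the non-negativity the
        chi-square filter requires).
    seed : int
        Seed of the single RNG stream that drives generation.
    """

    n_samples: int = 200
    n_informative: int = 10
    n_redundant: int = 20
    n_noise: int = 170
    effect_size: float = 2.0
    redundancy_noise_sd: float = 0.2
    class_balance: float = 0.5
    nonnegative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_features == 0:
            raise ValueError("feature budget is zero: need at least one feature")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features require at least one informative source")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(f"class_balance must be in (0, 1), got {self.class_balance}")
        if self.effect_size < 0 or self.redundancy_noise_sd < 0:
            raise ValueError("effect_size and redundancy_noise_sd must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    """Which columns were planted with signal.

    ``informative_ids`` are disjoint from the keys of ``redundant_map``; the
    values of ``redundant_map`` point back into ``informative_ids``.
    """

    informative_ids: set[str] = field(default_factory=set)
    redundant_map: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_ids": sorted(self.informative_ids),
                "redundant_map": dict(sorted(self.redundant_map.items())),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(set(obj["informative_ids"]), dict(obj["redundant_map"]))


def make_feature_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate a planted two-class feature matrix.

    Returns ``(X, y, truth)`` where ``X`` is an ``n_samples x n_features``
    DataFrame (rows indexed by sample id, columns named ``f00000`` ...),
    ``y`` is a 0/1 Series aligned with ``X`` (1 = malignant-like class) and
    ``truth`` records the planted structure.

    The RNG stream is consumed in a fixed, documented order — informative
    block, redundant slopes, redundant source assignment, redundant noise,
    noise block — so equal specs give bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n1 = int(round(spec.class_balance * n))
    n1 = min(max(n1, 1), n - 1) if n >= 2 else n1
    y = np.zeros(n, dtype=int)
    y[n - n1 :] = 1

    names = [f"f{i:05d}" for i in range(spec.n_features)]
    inf_names = names[: spec.n_informative]
    red_names = names[spec.n_informative : spec.n_informative + spec.n_redundant]
    blocks = []

    # informative: unit-sd Gaussians with per-class means +/- effect_size/2
    if spec.n_informative:
        shift = np.where(y == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
        informative = rng.standard_normal((n, spec.n_informative)) + shift[:, None]
        blocks.append(informative)

    truth = GroundTruth(informative_ids=set(inf_names))

    if spec.n_redundant:
        slopes = rng.uniform(0.5, 1.5, size=spec.n_redundant)
        sources = rng.integers(0, spec.n_informative, size=spec.n_redundant)
        noise = rng.standard_normal((n, spec.n_redundant)) * spec.redundancy_noise_sd
        redundant = informative[:, sources] * slopes[None, :] + noise
        blocks.append(redundant)
        truth.redundant_map = {
            red: inf_names[src] for red, src in zip(red_names, sources)
        }

    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))

    X = np.hstack(blocks)
    if spec.nonnegative:
        X = np.maximum(X, 0.0)

    index = pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id")
    return (
        pd.DataFrame(X, index=index, columns=names),
        pd.Series(y, index=index, name="label"),
        truth,
    )


# ---------------------------------------------------------------------------
# toy cell images


def make_toy_cell_images(
    n_per_class: int, side: int = 64, seed: int = 0
) -> tuple[np.ndarray, pd.Series]:
    """Draw toy "cell" images: smooth discs (class 0) vs perturbed discs
    with interior cavities (class 1).

    Class 0 mimics a benign lymphocyte — a filled disc with a smooth, near
    circular contour.  Class 1 mimics a lymphoblast — the disc boundary is
    modulated by random harmonics (irregular nuclear envelope) and one or
    more small bright cavities (vacuole-like) are punched into the interior.

    Returns an ``(2*n_per_class, side, side, 3)`` float array in [0, 1] and
    the matching 0/1 label Series.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if side < 32:
        raise ValueError(f"side must be >= 32, got {side}")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    images = np.empty((2 * n_per_class, side, side, 3), dtype=float)
    labels = np.array([0] * n_per_class + [1] * n_per_class)

    for i, lab in enumerate(labels):
        cx, cy = side / 2 + rng.uniform(-2, 2, size=2)
        base_r = side * rng.uniform(0.28, 0.34)
        theta = np.arctan2(yy - cy, xx - cx)
        r = np.hypot(xx - cx, yy - cy)
        radius = np.full_like(theta, base_r)
        if lab == 1:
            # irregular envelope: sum of random low-order harmonics
            for k in range(3, 7):
                amp = rng.uniform(0.05, 0.12) * base_r
                phase = rng.uniform(0, 2 * np.pi)
                radius = radius + amp * np.sin(k * theta + phase)
        disc = (r <= radius).astype(float)
        if lab == 1:
            n_cav = rng.integers(1, 4)
            for _ in range(n_cav):
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.2, 0.55) * base_r
                ccx, ccy = cx + dist * np.cos(ang), cy + dist * np.sin(ang)
                crad = rng.uniform(0.08, 0.16) * base_r
                disc[np.hypot(xx - ccx, yy - ccy) <= crad] = 0.0

        # stain-like rendering: purple disc on pale background, mild texture
        texture = 0.05 * rng.standard_normal((side, side))
        img = np.empty((side, side, 3))
        img[..., 0] = 0.90 - 0.45 * disc
        img[..., 1] = 0.88 - 0.62 * disc
        img[..., 2] = 0.92 - 0.25 * disc
        img += texture[..., None] * disc[..., None]
        images[i] = np.clip(img, 0.0, 1.0)

    index = pd.Index([f"img{i:03d}" for i in range(len(labels))], name="sample_id")
    return images, pd.Series(labels, index=index, name="label")


# ---------------------------------------------------------------------------
# on-disk formats (delimited matrix + two-column labels + JSON ground truth)


def save_dataset(
    out_dir: str | Path,
    X: pd.DataFrame,
    y: pd.Series,
    truth: GroundTruth | None = None,
) -> None:
    """Write ``features.csv`` (first column sample id), ``labels.csv`` and,
    when ground truth is known, ``ground_truth.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X.to_csv(out / "features.csv")
    y.to_csv(out / "labels.csv")
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())


def load_dataset(in_dir: str | Path) -> tuple[pd.DataFrame, pd.Series, GroundTruth | None]:
    path = Path(in_dir)
    X = pd.read_csv(path / "features.csv", index_col=0)
    y = pd.read_csv(path / "labels.csv", index_col=0).iloc[:, 0]
    gt_path = path / "ground_truth.json"
    truth = GroundTruth.from_json(gt_path.read_text()) if gt_path.exists() else None
    return X, y, truth


def save_toy_images(out_dir: str | Path, images: np.ndarray, labels: pd.Series) -> list[Path]:
    """Write toy images as PNGs into class-named subdirectories."""
    from skimage.io import imsave

    out = Path(out_dir)
    paths = []
    for (sample_id, lab), img in zip(labels.items(), images):
        sub = out / f"class_{lab}"
        sub.mkdir(parents=True, exist_ok=True)
        p = sub / f"{sample_id}.png"
        imsave(p, (img * 255).astype(np.uint8), check_contrast=False)
        paths.append(p)
    return paths
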