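"""Synthetic multi-subject datasets for exercising the full stack offline.

Two generators: (1) feature-space datasets in which each class occupies a
low-dimensional linear subspace, perturbed by a fixed per-subject offset
and isotropic Gaussian noise — the structure the dictionary-pair model
assumes; (2) raw oscillatory multichannel trials in which each class
carries elevated power in an assigned frequency band, for the feature
extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import FeatureDataset, SubjectRecord
from .features import DEFAULT_BANDS, BandSpec, RawTrial

_MAX_BASIS_RETRIES = 1000


@dataclass
class SubspaceSpec:
    K: int = 3
    p: int = 60
    r: int = 8
    n_per_class_per_subject: int = 40
    N_subjects: int = 10
    subject_shift_scale: float = 0.0
    noise_sigma: float = 0.05
    class_separation: float = 0.5  # principal-angle floor, radians
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r > self.p:
            raise ValueError("subspace dimension r cannot exceed p")
        if self.N_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class OscillatorySpec:
    channels: int = 4
    fs: float = 128.0
    duration: float = 10.0
    class_bands: tuple[BandSpec, ...] = (DEFAULT_BANDS[1], DEFAULT_BANDS[2])
    amplitude_ratio: float = 5.0
    noise_sigma: float = 1.0
    trials_per_class: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        nyq_ceiling = 0.99 * self.fs / 2
        for band in self.class_bands:
            if band is not None and band.lo >= min(band.hi, nyq_ceiling):
                raise ValueError(
                    f"band {band.name!r} does not fit below Nyquist at fs={self.fs}"
                )


def _min_principal_angle(U: np.ndarray, V: np.ndarray) -> float:
    """Smallest principal angle between the column spaces of U and V."""
    s = np.linalg.svd(U.T @ V, compute_uv=False)
    return float(np.arccos(np.clip(s.max(), -1.0, 1.0)))


def draw_separated_bases(
    K: int, p: int, r: int, min_angle: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Rejection-sample K orthonormal p x r bases whose pairwise smallest
    principal angle is at least ``min_angle``."""
    for _ in range(_MAX_BASIS_RETRIES):
        bases = [np.linalg.qr(rng.standard_normal((p, r)))[0] for _ in range(K)]
        ok = all(
            _min_principal_angle(bases[i], bases[j]) >= min_angle
            for i in range(K)
            for j in range(i + 1, K)
        )
        if ok:
            return bases
    raise RuntimeError(
        f"could not draw {K} subspaces of dim {r} in R^{p} with pairwise "
        f"principal angle >= {min_angle}; try a larger p or smaller r"
    )


def make_subspace_dataset(spec: SubspaceSpec) -> FeatureDataset:
    """Multi-subject dataset: x = U_k c + o_s + eps, with c ~ N(0, I),
    o_s a fixed per-subject offset and eps isotropic Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    bases = draw_separated_bases(spec.K, spec.p, spec.r, spec.class_separation, rng)
    subjects = []
    width = len(str(spec.N_subjects))
    for s in range(spec.N_subjects):
        offset = rng.standard_normal(spec.p)
        norm = np.linalg.norm(offset)
        offset = spec.subject_shift_scale * (offset / norm if norm > 0 else offset)
        cols, labels = [], []
        for k in range(spec.K):
            C = rng.standard_normal((spec.r, spec.n_per_class_per_subject))
            X = bases[k] @ C
            X += offset[:, None]
            X += spec.noise_sigma * rng.standard_normal(X.shape)
            cols.append(X)
            labels.append(np.full(spec.n_per_class_per_subject, k + 1))
        subjects.append(
            SubjectRecord(
                subject_id=f"sub{s + 1:0{width}d}",
                X=np.hstack(cols),
                labels=np.concatenate(labels),
            )
        )
    return FeatureDataset(subjects, K=spec.K)


def make_oscillatory_trials(spec: OscillatorySpec) -> list[RawTrial]:
    """Raw trials in which class k's channels carry a sinusoid at a random
    frequency inside its assigned band, on top of broadband noise.  The
    label of a noise-only class (``class_bands`` entry None) is supported by
    passing None in the tuple."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    nyq_ceiling = 0.99 * spec.fs / 2
    trials = []
    for k, band in enumerate(spec.class_bands):
        for j in range(spec.trials_per_class):
            data = spec.noise_sigma * rng.standard_normal((spec.channels, n))
            if band is not None:
                hi = min(band.hi, nyq_ceiling)
                freq = rng.uniform(band.lo, hi)
                amp = spec.amplitude_ratio * spec.noise_sigma
                phases = rng.uniform(0, 2 * np.pi, size=spec.channels)
                data += amp * np.sin(
                    2 * np.pi * freq * t[None, :] + phases[:, None]
                )
            trials.append(
                RawTrial(
                    data=data,
                    fs=spec.fs,
                    subject_id=f"sim{j + 1}",
                    label=k + 1,
                )
            )
    return trials


#: Pinned settings for the fixture on which the default hyperparameters are
#: measurably suboptimal: small class separation, moderate noise, per-subject
#: shifts and a true subspace dimension far from the default dictionary size.
_ADVERSARIAL_SPEC = dict(
    K=3,
    p=24,
    r=4,
    n_per_class_per_subject=15,
    N_subjects=5,
    subject_shift_scale=1.5,
    noise_sigma=0.6,
    class_separation=0.25,
)


def make_adversarial_default_dataset(seed: int = 0) -> FeatureDataset:
    """A small subspace dataset tuned so the reference defaults
    (m=32, tau=0.03, lam=0.003, gam=0.0001) are suboptimal while other
    decodable parameter settings reach higher LOSO accuracy."""
    return make_subspace_dataset(SubspaceSpec(seed=seed, **_ADVERSARIAL_SPEC))
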