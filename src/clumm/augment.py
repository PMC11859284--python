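"""Random augmentations producing the positive view pair for contrastive training.

Two transforms are composed per sample: additive Gaussian jitter (t1) and
multiplication by a single Gaussian scale factor (t2).  View assignment is
asymmetric by construction — view 1 is always the jittered sample, view 2
the scaled one.

A note on the scale factor's centre: the transform is eta ~ N(scale_center,
scale_sd^2) with a default centre of 1.0, so the scaled view preserves the
sample in expectation.  A zero-centred factor — which annihilates the signal
in expectation and leaves the positive pair uninformative — is available
behind ``paper_literal_scaling=True`` for anyone wanting that exact
behaviour; see the methods note for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "ViewPair", "jitter", "scale", "make_view_pair"]


@dataclass(frozen=True)
class AugmentConfig:
    jitter_sd: float = 0.5
    scale_sd: float = 0.2
    scale_center: float = 1.0
    paper_literal_scaling: bool = False

    def __post_init__(self):
        if self.jitter_sd < 0 or self.scale_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def effective_scale_center(self) -> float:
        return 0.0 if self.paper_literal_scaling else self.scale_center


@dataclass(frozen=True)
class ViewPair:
    """Two correlated views of one source row: (jittered, scaled)."""

    view1: np.ndarray
    view2: np.ndarray
    source_row: int = -1


def jitter(v: np.ndarray, rng: np.random.Generator, jitter_sd: float = 0.5) -> np.ndarray:
    """t1: add elementwise i.i.d. Gaussian noise N(0, jitter_sd^2)."""
    v = np.asarray(v, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ValueError("input vector must be finite")
    if jitter_sd == 0:
        return v.copy()
    return v + rng.normal(0.0, jitter_sd, size=v.shape)


def scale(
    v: np.ndarray,
    rng: np.random.Generator,
    scale_sd: float = 0.2,
    scale_center: float = 1.0,
    paper_literal: bool = False,
) -> np.ndarray:
    """t2: multiply the whole vector by one scalar factor eta.

    eta ~ N(scale_center, scale_sd^2); with ``paper_literal`` the centre is
    forced to zero.
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ValueError("input vector must be finite")
    center = 0.0 if paper_literal else scale_center
    eta = rng.normal(center, scale_sd) if scale_sd > 0 else center
    return v * eta


def make_view_pair(
    v: np.ndarray, config: AugmentConfig, rng: np.random.Generator, source_row: int = -1
) -> ViewPair:
    """Apply t1 and t2 to one sample, yielding the positive pair."""
    view1 = jitter(v, rng, config.jitter_sd)
    view2 = scale(
        v,
        rng,
        config.scale_sd,
        config.scale_center,
        paper_literal=config.paper_literal_scaling,
    )
    return ViewPair(view1=view1, view2=view2, source_row=source_row)


def augment_batch(
    batch: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized view-pair generation for a (b, d) batch.

    Draw order is per-sample (jitter noise then scale factor) so results
    match ``make_view_pair`` applied row by row with the same stream.
    """
    batch = np.asarray(batch, dtype=np.float64)
    views1 = np.empty_like(batch)
    views2 = np.empty_like(batch)
    for i, row in enumerate(batch):
        pair = make_view_pair(row, config, rng, source_row=i)
        views1[i] = pair.view1
        views2[i] = pair.view2
    return views1, views2
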