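"""Learned correction of the chaining ANI estimate.

Chaining can slightly overestimate ANI near chain edges: mutated k-mers
at the ends of a homologous region may be excluded from the chain, so
the anchors/seeds ratio inside the chain is biased high.  A gradient-
boosted regression tree (absolute-deviation loss) maps five features of
a comparison — the chaining ANI, the spread of the per-chunk ANI
estimates, the 90th-percentile contig lengths of both genomes, and the
mean chain length — to a corrected ANI.

The correction is deliberately conservative: it fires only above 90%
ANI with more than 150 kb aligned, is auto-enabled only at seed rates
``c >= 70`` (bias is negligible for denser seeding), and is clamped to
±0.02 of the raw estimate.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .estimate import AniResult
from .params import SketchParams
from .sketch import GenomeSketch

__all__ = [
    "DebiasFeatures",
    "DebiasModel",
    "apply_debias",
    "extract_features",
    "load_model",
    "save_model",
    "select_model",
    "train_debias",
]

FEATURE_ORDER = (
    "ani",
    "chunk_ani_sd",
    "ref_p90_contig_len",
    "query_p90_contig_len",
    "mean_chain_len",
)
MODEL_FORMAT_VERSION = 1
#: Maximum correction magnitude; debiasing is a small edge-effect fix by
#: construction, so larger shifts indicate extrapolation and are clamped.
MAX_CORRECTION = 0.02


@dataclass(frozen=True)
class DebiasFeatures:
    ani: float
    chunk_ani_sd: float
    ref_p90_contig_len: float
    query_p90_contig_len: float
    mean_chain_len: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_ORDER], dtype=float)


@dataclass
class DebiasModel:
    """Fitted correction model plus the metadata needed to refuse
    incompatible inputs."""

    estimator: GradientBoostingRegressor
    c: int
    feature_order: tuple[str, ...] = FEATURE_ORDER
    version: int = MODEL_FORMAT_VERSION
    holdout_mad: float | None = None

    def predict(self, features: DebiasFeatures) -> float:
        if self.feature_order != FEATURE_ORDER or self.version != MODEL_FORMAT_VERSION:
            raise ValueError(
                "debias model feature order/version incompatible with this build "
                f"(model: {self.feature_order} v{self.version})"
            )
        return float(self.estimator.predict(features.as_array()[None, :])[0])


def extract_features(
    result: AniResult, ref: GenomeSketch, query: GenomeSketch
) -> DebiasFeatures:
    """Feature vector for one comparison (requires a reported ANI).

    The chunk-ANI standard deviation is the population SD of the
    per-chunk estimates (0 when fewer than two chunks contributed);
    mean chain length is the mean reference-coordinate span of the
    selected chains.
    """
    if result.ani is None:
        raise ValueError("cannot extract debias features without an ANI estimate")
    chunk_anis = [s.ani for s in result.chunk_stats]
    sd = float(np.std(chunk_anis)) if len(chunk_anis) >= 2 else 0.0
    spans = [(c.anchors[-1].y - c.anchors[0].y) for c in result.chains]
    return DebiasFeatures(
        ani=result.ani,
        chunk_ani_sd=sd,
        ref_p90_contig_len=float(np.percentile(ref.contig_lengths, 90)),
        query_p90_contig_len=float(np.percentile(query.contig_lengths, 90)),
        mean_chain_len=float(np.mean(spans)) if spans else 0.0,
    )


def apply_debias(
    model: DebiasModel | None,
    result: AniResult,
    features: DebiasFeatures | None,
    params: SketchParams,
    force: bool | None = None,
) -> AniResult:
    """Apply the learned correction when every gate is open.

    Gates: a model is loaded; the raw ANI exceeds ``debias_ani_gate``;
    more than ``debias_min_aligned`` bases aligned; and the seed rate is
    coarse enough (``c >= debias_auto_c``) unless the user forces the
    correction on (``force=True``) or off (``force=False``).  Otherwise
    the result is returned unchanged with ``debiased=False``.
    """
    if model is None or result.ani is None or features is None or force is False:
        return result
    if result.ani <= params.debias_ani_gate:
        return result
    if result.aligned_bases <= params.debias_min_aligned:
        return result
    if params.c < params.debias_auto_c and not force:
        return result
    raw = result.ani
    corrected = model.predict(features)
    corrected = min(max(corrected, raw - MAX_CORRECTION), raw + MAX_CORRECTION)
    corrected = min(max(corrected, 0.0), 1.0)
    return replace(result, ani=corrected, debiased=True)


def select_model(models: list[DebiasModel], c_used: int) -> DebiasModel | None:
    """The model trained at the ``c`` nearest to the one in use
    (ties go to the smaller ``c``); None when no model is available."""
    if not models:
        return None
    return min(models, key=lambda m: (abs(m.c - c_used), m.c))


def train_debias(
    training_pairs: list[tuple[DebiasFeatures, float]],
    c: int = 125,
    rng_seed: int = 0,
    holdout_frac: float = 0.2,
    **gbr_params,
) -> DebiasModel:
    """Fit the correction on (features, true-ANI) pairs.

    Truth here is the known ``1 − θ`` of synthetic genome pairs.  A
    random held-out split measures the corrected mean absolute
    deviation, stored on the model for inspection.
    """
    if len(training_pairs) < 100:
        raise ValueError("need at least 100 training pairs to fit a debias model")
    y = np.array([t for _, t in training_pairs])
    if np.allclose(y, y[0]):
        raise ValueError("degenerate training set: constant target ANI")
    X = np.stack([f.as_array() for f, _ in training_pairs])

    rng = np.random.default_rng(rng_seed)
    idx = rng.permutation(len(y))
    n_hold = max(int(len(y) * holdout_frac), 1)
    hold, train = idx[:n_hold], idx[n_hold:]

    defaults = dict(loss="absolute_error", n_estimators=100, max_depth=3,
                    learning_rate=0.1, random_state=rng_seed % (2**31))
    defaults.update(gbr_params)
    est = GradientBoostingRegressor(**defaults)
    est.fit(X[train], y[train])
    mad = float(np.mean(np.abs(est.predict(X[hold]) - y[hold])))
    return DebiasModel(estimator=est, c=c, holdout_mad=mad)


def save_model(model: DebiasModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> DebiasModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, DebiasModel):
        raise ValueError(f"{path} does not contain a debias model")
    if model.feature_order != FEATURE_ORDER or model.version != MODEL_FORMAT_VERSION:
        raise ValueError(f"debias model {path} has incompatible feature order/version")
    return model
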