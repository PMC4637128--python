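"""Discriminant cell classification, kinetoplast brightness, and image- and
sample-level aggregation with titer estimation.

The cell classifier is a two-class linear discriminant over the axis
profile (bin means + bin standard deviations), trained on expert- or
simulator-labelled cells: class means, pooled covariance with a small ridge
term, decision by the linear score.  Anti-dsDNA positivity of a cell is the
fluorescence status of its kinetoplast, so "positive" here means the
kinetoplast band of the profile carries signal — nuclei and basal bodies
fluorescing alone must stay negative.

Brightness-to-titer mapping: the antibody titer is the highest dilution
still producing a positive reaction, and kinetoplast brightness at the
screening dilution falls off roughly in proportion to the remaining
antibody, so the median positive-cell brightness is mapped through
configurable monotone breakpoints onto the configured titer steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import AxisProfile, CellRecord
from .io import ConfigError, RunConfig

__all__ = [
    "CellCall",
    "ImageCall",
    "SampleResult",
    "TrainedClassifier",
    "train_classifier",
    "classify_cell",
    "extract_kinetoplast_brightness",
    "classify_image",
    "estimate_titer",
    "merge_dilutions",
    "parse_titer_label",
    "profile_feature_names",
]


@dataclass
class CellCall:
    """Per-cell verdict."""

    cell_id: int
    label: str  # "positive" | "negative" | "excluded"
    kinetoplast_brightness: float = 0.0
    posterior: float | None = None  # defined only for classified cells


@dataclass
class ImageCall:
    """Per-biochip verdict."""

    biochip_id: str
    verdict: str  # "positive" | "negative" | "rejected_qc"
    n_cells_total: int = 0
    n_cells_classified: int = 0
    fraction_positive: float = 0.0
    titer_estimate: str = "negative"
    confidence: float = 0.0
    sample_id: str = ""
    dilution_factor: float = 1.0
    reject_reason: str = ""


@dataclass
class SampleResult:
    """Dilution-merged final verdict for one sample."""

    sample_id: str
    verdict: str
    final_titer: str
    image_calls: list = field(default_factory=list)
    confidence: float = 0.0


def profile_feature_names(bins: int) -> list:
    return [f"p{i:02d}" for i in range(bins)] + [f"s{i:02d}" for i in range(bins)]


class TrainedClassifier:
    """Two-class linear discriminant with pooled, ridge-regularized covariance.

    Serializes to versioned JSON (class means, pooled covariance, feature
    list, training metadata) and reloads bit-stably.  ``n_predict_calls``
    counts discriminant evaluations, which makes the dark-image
    short-circuit of the pipeline directly observable.
    """

    RIDGE = 1e-6

    def __init__(self, class_means, pooled_cov, feature_names, metadata=None):
        self.class_means = np.asarray(class_means, dtype=np.float64)  # (2, d)
        self.pooled_cov = np.asarray(pooled_cov, dtype=np.float64)  # (d, d)
        self.feature_names = list(feature_names)
        self.metadata = dict(metadata or {})
        self.n_predict_calls = 0
        self._solve()

    def _solve(self):
        d = self.pooled_cov.shape[0]
        ridge = self.RIDGE * np.trace(self.pooled_cov) / d
        reg = self.pooled_cov + max(ridge, self.RIDGE) * np.eye(d)
        mu0, mu1 = self.class_means
        self.weights = np.linalg.solve(reg, mu1 - mu0)
        n0 = self.metadata.get("n_negative", 1)
        n1 = self.metadata.get("n_positive", 1)
        self.bias = float(
            -0.5 * self.weights @ (mu0 + mu1) + math.log(max(n1, 1) / max(n0, 1))
        )

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def decision_scores(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model {self.n_features}, input {X.shape[1]}"
            )
        self.n_predict_calls += X.shape[0]
        return X @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        return self.decision_scores(X) >= 0.0

    def posterior(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_scores(X)))

    def save(self, path) -> None:
        payload = {
            "format": "clift-lda",
            "version": 1,
            "feature_names": self.feature_names,
            "class_means": self.class_means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "clift-lda":
            raise ValueError(f"{path}: not a clift classifier file")
        return cls(
            payload["class_means"],
            payload["pooled_cov"],
            payload["feature_names"],
            payload.get("metadata"),
        )


def train_classifier(training_table: pd.DataFrame, cfg: RunConfig | None = None) -> TrainedClassifier:
    """Fit the linear discriminant on a labelled cell-profile table.

    The table is the per-cell feature CSV produced by the pipeline: profile
    mean columns ``p00..`` and sd columns ``s00..`` plus the binary
    ``kinetoplast_fluorescent`` label.  Cells flagged dark are excluded —
    at prediction time they never reach the model either.  Training
    accuracy is recorded in the model metadata.
    """
    cfg = cfg or RunConfig()
    names = profile_feature_names(cfg.profile_bins)
    missing = [n for n in names if n not in training_table.columns]
    if missing:
        raise ValueError(f"training table lacks feature columns: {missing[:4]}...")
    if "kinetoplast_fluorescent" not in training_table.columns:
        raise ValueError("training table lacks the kinetoplast_fluorescent label")
    table = training_table
    if "is_dark" in table.columns:
        table = table[~table["is_dark"].astype(bool)]
    y = table["kinetoplast_fluorescent"].astype(bool).to_numpy()
    X = table[names].to_numpy(dtype=np.float64)
    if y.all() or not y.any():
        raise ValueError("training table must contain both classes")

    X0, X1 = X[~y], X[y]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    s0 = (X0 - mu0).T @ (X0 - mu0)
    s1 = (X1 - mu1).T @ (X1 - mu1)
    pooled = (s0 + s1) / max(n0 + n1 - 2, 1)

    model = TrainedClassifier(
        [mu0, mu1],
        pooled,
        names,
        metadata={
            "n_negative": int(n0),
            "n_positive": int(n1),
            "profile_bins": cfg.profile_bins,
            "rng_seed": cfg.rng_seed,
        },
    )
    acc = float((model.predict(X) == y).mean())
    model.metadata["training_accuracy"] = acc
    model.n_predict_calls = 0
    return model


def classify_cell(
    profile: AxisProfile | None,
    record: CellRecord,
    model: TrainedClassifier | None,
    background_mean: float = 0.0,
    green=None,
    cfg: RunConfig | None = None,
) -> CellCall:
    """Assign one cell as positive/negative/excluded.

    QC-failed or orientation-unreliable cells are excluded.  Dark cells are
    negative by the threshold rule and bypass the discriminant entirely.
    """
    cfg = cfg or RunConfig()
    if not record.qc_pass or not record.orientation_reliable:
        return CellCall(cell_id=record.cell_id, label="excluded")
    brightness = 0.0
    if green is not None:
        brightness = extract_kinetoplast_brightness(
            profile, green, record, background_mean, cfg
        )
    if record.is_dark:
        return CellCall(
            cell_id=record.cell_id,
            label="negative",
            kinetoplast_brightness=brightness,
            posterior=1.0,
        )
    if model is None:
        raise ValueError("non-dark cell requires a trained classifier")
    x = profile.feature_vector()
    score = float(model.decision_scores(x)[0])
    positive = score >= 0.0
    post = 1.0 / (1.0 + math.exp(-abs(score)))
    return CellCall(
        cell_id=record.cell_id,
        label="positive" if positive else "negative",
        kinetoplast_brightness=brightness,
        posterior=post,
    )


def extract_kinetoplast_brightness(
    profile: AxisProfile | None,
    green,
    record: CellRecord,
    background_mean: float = 0.0,
    cfg: RunConfig | None = None,
) -> float:
    """Mean un-normalized green intensity over the kinetoplast band.

    The band covers canonical axis fractions 0.15-0.35 (the kinetoplast
    sits near 0.25, between basal body and nucleus); the background mean is
    subtracted and the result floored at 0 so it scales with the true
    fluorophore signal across dilutions.
    """
    cfg = cfg or RunConfig()
    if record.axis_u is None:
        return 0.0
    lo, hi = cfg.kinetoplast_band
    sel = (record.axis_u >= lo) & (record.axis_u <= hi)
    if not sel.any():
        return 0.0
    vals = green[record.pixel_rows[sel], record.pixel_cols[sel]]
    return float(max(vals.mean() - background_mean, 0.0))


def classify_image(cell_calls, cfg: RunConfig | None = None, *, biochip_id="",
                   sample_id="", dilution_factor=1.0) -> ImageCall:
    """Aggregate cell calls into an image verdict.

    fraction_positive = positives / classified; the verdict is positive when
    the fraction reaches the configured cutoff (ties resolve positive, the
    ">=" convention).  Confidence is a logistic transform of the distance of
    fraction_positive from the cutoff, scaled by the binomial standard error
    at the number of classified cells.
    """
    cfg = cfg or RunConfig()
    calls = list(cell_calls)
    classified = [c for c in calls if c.label in ("positive", "negative")]
    call = ImageCall(
        biochip_id=biochip_id,
        sample_id=sample_id,
        dilution_factor=dilution_factor,
        verdict="rejected_qc",
        n_cells_total=len(calls),
        n_cells_classified=len(classified),
    )
    if not classified:
        call.reject_reason = "no_evaluable_cells"
        return call
    n_pos = sum(1 for c in classified if c.label == "positive")
    frac = n_pos / len(classified)
    call.fraction_positive = frac
    cutoff = cfg.positive_cell_cutoff
    call.verdict = "positive" if frac >= cutoff else "negative"
    se = math.sqrt(max(cutoff * (1 - cutoff), 1e-12) / len(classified))
    call.confidence = 1.0 / (1.0 + math.exp(-abs(frac - cutoff) / se))
    call.titer_estimate = estimate_titer(calls, cfg, image_verdict=call.verdict)
    return call


def estimate_titer(cell_calls, cfg: RunConfig | None = None, *, image_verdict="positive") -> str:
    """Map the median positive-cell kinetoplast brightness onto a titer step.

    Negative images titrate to "negative".  Brightness at or above a
    breakpoint selects at least that step (">=" convention); a positive
    image below every breakpoint still reports the first step, since image
    positivity itself implies a titer at the screening dilution.
    """
    cfg = cfg or RunConfig()
    if len(cfg.brightness_to_titer_breakpoints) != len(cfg.titer_steps):
        raise ConfigError("breakpoints and titer_steps lengths differ")
    if image_verdict != "positive":
        return "negative"
    bright = [
        c.kinetoplast_brightness for c in cell_calls if c.label == "positive"
    ]
    if not bright:
        return cfg.titer_steps[0]
    med = float(np.median(bright))
    level = 0
    for j, bp in enumerate(cfg.brightness_to_titer_breakpoints):
        if med >= bp:
            level = j
    return cfg.titer_steps[level]


def parse_titer_label(label: str) -> float:
    """'1:320' -> 320.0; 'negative' -> 0."""
    if label == "negative":
        return 0.0
    left, _, right = label.partition(":")
    return float(right or left)


def titer_level(label: str, titer_steps) -> int:
    """Index of a titer label in the configured steps; 'negative' -> -1."""
    if label == "negative":
        return -1
    return list(titer_steps).index(label)


def _implied_level(dilution_factor: float, titer_steps) -> int:
    """Titer level implied by a positive image at a given dilution.

    The screening dilution (factor 1) corresponds to the first titer step;
    a positive reaction at factor f implies a titer of at least
    first_step * f, matched to the nearest configured step in log space.
    """
    base = parse_titer_label(titer_steps[0])
    implied = base * dilution_factor
    values = [parse_titer_label(t) for t in titer_steps]
    logs = [abs(math.log(v) - math.log(implied)) for v in values]
    j = int(np.argmin(logs))
    if logs[j] > math.log(1.5):
        # no step close to this dilution: fall back to the largest step
        # not exceeding it
        j = max([i for i, v in enumerate(values) if v <= implied * 1.05] or [0])
    return j


def merge_dilutions(image_calls, cfg: RunConfig | None = None) -> SampleResult:
    """Merge the per-dilution image calls of one sample into a final result.

    The sample is positive iff any dilution is positive.  The final titer is
    the maximum of the per-image titer estimates and the titer implied by
    the highest positive dilution; confidence is the minimum over the
    contributing (non-rejected) images.
    """
    cfg = cfg or RunConfig()
    calls = list(image_calls)
    if not calls:
        raise ValueError("merge_dilutions requires at least one image call")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"conflicting sample_ids: {sorted(sample_ids)}")
    sample_id = calls[0].sample_id
    usable = [c for c in calls if c.verdict != "rejected_qc"]
    positive = [c for c in usable if c.verdict == "positive"]
    if not usable:
        return SampleResult(
            sample_id=sample_id, verdict="rejected_qc", final_titer="negative",
            image_calls=calls, confidence=0.0,
        )
    confidence = min(c.confidence for c in usable)
    if not positive:
        return SampleResult(
            sample_id=sample_id, verdict="negative", final_titer="negative",
            image_calls=calls, confidence=confidence,
        )
    levels = []
    for c in positive:
        levels.append(titer_level(c.titer_estimate, cfg.titer_steps))
        levels.append(_implied_level(c.dilution_factor, cfg.titer_steps))
    final = cfg.titer_steps[max(levels)]
    return SampleResult(
        sample_id=sample_id, verdict="positive", final_titer=final,
        image_calls=calls, confidence=confidence,
    )
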