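"""Leave-one-subject-out evaluation of the five decoding variants.

Variants (all classified by the shared multi-task linear stage):

* ``BP`` — log band power of the 8-30 Hz signal per channel; no spatial
  filtering.
* ``RCSP`` — regularized CSP on the single 8-30 Hz band, log-variance
  features.
* ``FBCSP`` — plain CSP per constant-filter-bank band, all-band features
  concatenated (no mutual-information selection; documented simplification).
* ``CFB-RCSP`` / ``VFB-RCSP`` — regularized CSP per subband of the
  constant / variable filter bank, Fisher-ξ optimal-subband selection.

Each subject is held out in turn; every fitted quantity (spatial filters,
subband choice, regularization strength, classifier prior) is estimated from
the remaining subjects only.  In calibration mode a leading fraction of the
target's trials may additionally enter fitting and is excluded from testing;
an audit trail records exactly what each fold was fitted on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .alignment import euclidean_align
from .epochs import EpochSet, bandpass_filter, crop_epochs
from .filterbank import BandSpec, decompose, make_cfb, make_vfb
from .mtl import add_bias, mtl_fit, mtl_predict, update_ws
from .spatial import (
    ClassCovariances,
    csp_fit,
    logvar_from_covariances,
    rcsp_covariance,
    trial_covariances,
)
from .subband import (
    DEFAULT_A_GRID,
    DEFAULT_B_GRID,
    _inner_cv_accuracy,
    select_optimal_band,
)

__all__ = [
    "VARIANTS",
    "MethodConfig",
    "EvalResult",
    "accuracy",
    "cohen_kappa",
    "loso_evaluate",
    "run_variant",
]

VARIANTS = ("BP", "RCSP", "FBCSP", "CFB-RCSP", "VFB-RCSP")

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class MethodConfig:
    """Full configuration of one evaluation run."""

    variant: str
    apply_ea: bool = True
    bandpass: tuple[float, float] = (8.0, 30.0)
    bandpass_order: int = 6
    crop: tuple[float, float] | None = None
    n_pairs: int = 2
    calibration: bool = False
    calibration_fraction: float = 0.2
    beta_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
    gamma_grid: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1)
    a_grid: tuple[float, ...] = DEFAULT_A_GRID
    b_grid: tuple[float, ...] = DEFAULT_B_GRID
    k_bands: int = 1
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid variants: {', '.join(VARIANTS)}"
            )
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must lie in (0, 1)")

    def band_spec(self) -> BandSpec:
        if self.variant in ("BP", "RCSP"):
            return BandSpec(bands=(tuple(self.bandpass),), scheme_name="broadband")
        if self.variant in ("FBCSP", "CFB-RCSP"):
            return make_cfb()
        return make_vfb()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class EvalResult:
    """Per-subject confusions plus cohort-level accuracy and kappa."""

    variant: str
    per_subject: list[dict[str, Any]]
    mean_accuracy: float
    sd_accuracy: float
    mean_kappa: float
    sd_kappa: float
    provenance: dict[str, Any] = field(default_factory=dict)
    audit: list[dict[str, Any]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": r["subject_id"],
                "accuracy": round(r["accuracy"], 2),
                "kappa": round(r["kappa"], 2),
                "n_test": r["n_test"],
            }
            for r in self.per_subject
        ]
        rows.append(
            {
                "subject": "mean",
                "accuracy": round(self.mean_accuracy, 2),
                "kappa": round(self.mean_kappa, 2),
                "n_test": int(sum(r["n_test"] for r in self.per_subject)),
            }
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(confusion: np.ndarray) -> float:
    """Percent correct from a 2x2 confusion matrix (rows true, cols predicted)."""
    confusion = np.asarray(confusion, float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(confusion) / total


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement; 0 when expected agreement is 1."""
    confusion = np.asarray(confusion, float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(confusion) / total
    row = confusion.sum(axis=1) / total
    col = confusion.sum(axis=0) / total
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    conf = np.zeros((2, 2), dtype=int)
    for i, true_k in enumerate((+1, -1)):
        for j, pred_k in enumerate((+1, -1)):
            conf[i, j] = int(np.sum((y_true == true_k) & (y_pred == pred_k)))
    return conf


# ---------------------------------------------------------------------------
# cached per-band trial covariances
# ---------------------------------------------------------------------------

@dataclass
class _SubjectCache:
    subject_id: str
    labels: np.ndarray
    covs: list[np.ndarray]       # per band, (n_trials, c, c): X Xᵀ / n_samples
    norm_covs: list[np.ndarray]  # per band, trace-normalized


def _preprocess(epochs: EpochSet, config: MethodConfig) -> EpochSet:
    low, high = config.bandpass
    out = bandpass_filter(epochs, low, high, order=config.bandpass_order)
    if config.crop is not None:
        out = crop_epochs(out, *config.crop)
    if config.apply_ea:
        out = euclidean_align(out).aligned
    return out


def _build_cache(epochs: EpochSet, spec: BandSpec, config: MethodConfig) -> _SubjectCache:
    if epochs.labels is None:
        raise ValueError(f"subject {epochs.subject_id!r} has no labels")
    covs, norm_covs = [], []
    for band_epochs in decompose(epochs, spec):
        C = trial_covariances(band_epochs, normalize=False)
        traces = np.trace(C, axis1=1, axis2=2)
        covs.append(C)
        norm_covs.append(C / np.maximum(traces, _VAR_FLOOR)[:, None, None])
    return _SubjectCache(
        subject_id=epochs.subject_id, labels=epochs.labels.copy(),
        covs=covs, norm_covs=norm_covs,
    )


def _class_mean(norm_covs: np.ndarray, labels: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    mask = labels == k
    if not mask.any():
        raise ValueError(f"no trials of class {k}")
    mean = norm_covs[mask].mean(axis=0)
    return 0.5 * (mean + mean.T), int(mask.sum())


def _rcsp_band_filters(
    src_norm: np.ndarray, src_labels: np.ndarray,
    cal_norm: np.ndarray | None, cal_labels: np.ndarray | None,
    beta: float, gamma: float, n_pairs: int,
):
    """RCSP filters for one band from cached covariances."""
    regs = {}
    for k in (+1, -1):
        C_s, n_s = _class_mean(src_norm, src_labels, k)
        C_t, n_t = (None, 0)
        if cal_norm is not None and beta > 0:
            C_t, n_t = _class_mean(cal_norm, cal_labels, k)
        cc = ClassCovariances(C_target=C_t, C_source=C_s,
                              n_target=n_t, n_source=n_s, klass=k)
        regs[k] = rcsp_covariance(cc, beta, gamma)
    model = csp_fit(regs[+1], regs[-1], n_pairs=n_pairs)
    model.beta, model.gamma = beta, gamma
    return model


def _bp_features(covs: np.ndarray) -> np.ndarray:
    """Log mean-square amplitude per channel from raw per-trial covariances."""
    power = np.diagonal(covs, axis1=1, axis2=2)
    return np.log(np.maximum(power, _VAR_FLOOR))


# ---------------------------------------------------------------------------
# the harness
# ---------------------------------------------------------------------------

def loso_evaluate(cohort: Sequence[EpochSet], config: MethodConfig) -> EvalResult:
    """Run the configured variant with leave-one-subject-out folds.

    Preprocessing (band-pass, optional crop, per-subject Euclidean
    alignment) is label-free and target-independent, so it is applied once
    per subject before the folds.  Everything label- or target-dependent is
    fitted inside each fold from source subjects (plus declared calibration
    trials) only.
    """
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least two subjects")
    spec = config.band_spec()
    processed = [_preprocess(s, config) for s in cohort]
    caches = [_build_cache(s, spec, config) for s in processed]
    for cache in caches:
        if not (np.any(cache.labels == 1) and np.any(cache.labels == -1)):
            raise ValueError(f"subject {cache.subject_id!r} lacks one class")

    per_subject: list[dict[str, Any]] = []
    folds_prov: list[dict[str, Any]] = []
    audit: list[dict[str, Any]] = []
    for t, target in enumerate(caches):
        sources = [c for i, c in enumerate(caches) if i != t]
        fold = _run_fold(target, sources, spec, config)
        per_subject.append(fold["result"])
        folds_prov.append(fold["provenance"])
        audit.append(fold["audit"])

    accs = np.array([r["accuracy"] for r in per_subject])
    kappas = np.array([r["kappa"] for r in per_subject])
    return EvalResult(
        variant=config.variant,
        per_subject=per_subject,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_kappa=float(kappas.mean()),
        sd_kappa=float(kappas.std(ddof=1)) if len(kappas) > 1 else 0.0,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "band_scheme": spec.scheme_name,
            "bands_hz": [list(b) for b in spec],
            "folds": folds_prov,
        },
        audit=audit,
    )


def _run_fold(
    target: _SubjectCache,
    sources: list[_SubjectCache],
    spec: BandSpec,
    config: MethodConfig,
) -> dict[str, Any]:
    n_bands = len(spec)
    src_labels = np.concatenate([s.labels for s in sources])
    src_norm = [
        np.concatenate([s.norm_covs[b] for s in sources]) for b in range(n_bands)
    ]
    src_covs = [
        np.concatenate([s.covs[b] for s in sources]) for b in range(n_bands)
    ]

    # declared target calibration trials (leading block; excluded from test)
    n_cal = 0
    cal_norm = cal_labels = None
    if config.calibration:
        n_cal = int(round(config.calibration_fraction * target.labels.size))
        cal_labels = target.labels[:n_cal]
        cal_norm = [nc[:n_cal] for nc in target.norm_covs]
    test_slice = slice(n_cal, None)
    y_test = target.labels[test_slice]

    chosen: dict[str, Any] = {"beta": None, "gamma": None, "a": None, "b": None,
                              "selected_bands": None, "inner_cv_accuracy": None}

    if config.variant == "BP":
        source_feats = [_bp_features(s.covs[0]) for s in sources]
        test_feat = _bp_features(target.covs[0][test_slice])
        cal_feat = _bp_features(target.covs[0][:n_cal]) if n_cal else None
    elif config.variant == "FBCSP":
        models = [
            _rcsp_band_filters(src_norm[b], src_labels, None, None,
                               beta=0.0, gamma=0.0, n_pairs=config.n_pairs)
            for b in range(n_bands)
        ]
        source_feats = [_band_concat(s, models, range(n_bands)) for s in sources]
        test_feat = _band_concat_slice(target, models, range(n_bands), test_slice)
        cal_feat = _band_concat_slice(target, models, range(n_bands), slice(0, n_cal)) if n_cal else None
        chosen.update(beta=0.0, gamma=0.0, selected_bands=list(range(1, n_bands + 1)))
    else:  # RCSP, CFB-RCSP, VFB-RCSP
        candidates = (
            [(b, g) for b in config.beta_grid for g in config.gamma_grid]
            if config.calibration
            else [(0.0, g) for g in config.gamma_grid]
        )
        best = None
        for beta, gamma in candidates:
            models = [
                _rcsp_band_filters(src_norm[b], src_labels, cal_norm[b] if cal_norm else None,
                                   cal_labels, beta, gamma, config.n_pairs)
                for b in range(n_bands)
            ]
            band_feats = [
                logvar_from_covariances(np.concatenate([s.norm_covs[b] for s in sources]),
                                        models[b].W)
                for b in range(n_bands)
            ]
            if config.variant == "RCSP":
                score = _inner_cv_accuracy(band_feats[0], src_labels, seed=config.seed)
                cand = {"models": models, "bands": [1], "a": None, "b": None,
                        "score": score, "beta": beta, "gamma": gamma}
            else:
                sb = select_optimal_band(
                    band_feats, src_labels,
                    grid_a=config.a_grid, grid_b=config.b_grid,
                    k_bands=config.k_bands, seed=config.seed,
                )
                cand = {"models": models, "bands": sorted(sb.selected),
                        "a": sb.a, "b": sb.b, "score": sb.cv_accuracy,
                        "beta": beta, "gamma": gamma}
            if best is None or cand["score"] > best["score"]:
                best = cand
        models = best["models"]
        band_idx = [b - 1 for b in best["bands"]]
        source_feats = [_band_concat(s, models, band_idx) for s in sources]
        test_feat = _band_concat_slice(target, models, band_idx, test_slice)
        cal_feat = _band_concat_slice(target, models, band_idx, slice(0, n_cal)) if n_cal else None
        chosen.update(
            beta=best["beta"], gamma=best["gamma"], a=best["a"], b=best["b"],
            selected_bands=best["bands"], inner_cv_accuracy=best["score"],
            selected_bands_hz=[list(spec.bands[b]) for b in band_idx],
        )

    # --- shared multi-task classification stage ---
    tasks = [
        (add_bias(F), s.labels.astype(float)) for F, s in zip(source_feats, sources)
    ]
    model = mtl_fit(tasks, lam=config.lam)
    if n_cal:
        w_t = update_ws(add_bias(cal_feat), cal_labels.astype(float),
                        model.mu, model.sigma, config.lam)
        scores = add_bias(test_feat) @ w_t
        y_pred = np.where(scores >= 0, 1, -1)
    else:
        y_pred = mtl_predict(add_bias(test_feat), model)

    conf = _confusion(y_test, y_pred)
    return {
        "result": {
            "subject_id": target.subject_id,
            "confusion": conf,
            "accuracy": accuracy(conf),
            "kappa": cohen_kappa(conf),
            "n_test": int(y_test.size),
        },
        "provenance": {
            "target": target.subject_id,
            **{k: v for k, v in chosen.items()},
            "lam": config.lam,
            "mtl_converged": model.converged,
            "mtl_iterations": len(model.history),
        },
        "audit": {
            "target": target.subject_id,
            "fitted_on": [s.subject_id for s in sources],
            "target_trials_in_fit": n_cal,
            "spatial_stage": config.variant != "BP",
        },
    }


def _band_concat(cache: _SubjectCache, models, band_idx) -> np.ndarray:
    return np.concatenate(
        [logvar_from_covariances(cache.norm_covs[b], models[b].W) for b in band_idx],
        axis=1,
    )


def _band_concat_slice(cache: _SubjectCache, models, band_idx, sl: slice) -> np.ndarray:
    return np.concatenate(
        [logvar_from_covariances(cache.norm_covs[b][sl], models[b].W) for b in band_idx],
        axis=1,
    )


def run_variant(cohort: Sequence[EpochSet], variant: str, **overrides: Any) -> EvalResult:
    """Evaluate one named variant with default settings (overridable)."""
    config = MethodConfig(variant=variant, **overrides)
    return loso_evaluate(cohort, config)
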