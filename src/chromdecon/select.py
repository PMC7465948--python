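"""Component-count selection and resolved-component extraction.

For each interval the component count R is swept over a range (default
1-7) and the smallest R passing all acceptance rules is chosen:

* model fit > 90%,
* core consistency > 90%,
* converged ALS,
* balanced residuals (no member above 3x the median residual norm).

Parsimony (smallest passing R, not best-fit R) is deliberate:
overfactoring splits genuine spectra across components. Intervals where no
candidate passes are flagged for manual review, possibly with an extended
R range (badly overloaded peaks can need more components than the default
cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chrom_io import LibrarySpectrum, MAX_RELATIVE_INTENSITY
from .intervals import IntervalCube
from .parafac2 import FitSettings, Parafac2Model, fit_parafac2, residual_summary

__all__ = [
    "SelectionRules",
    "ModelSweepResult",
    "ComponentRecord",
    "sweep_models",
    "extract_components",
    "label_baseline",
    "DEFAULT_BACKGROUND_IONS",
]

# common column-bleed / siloxane fragment ions
DEFAULT_BACKGROUND_IONS = (207, 281, 355)

FIT_THRESHOLD = 90.0  # percent
CORE_CONSISTENCY_THRESHOLD = 90.0  # percent


@dataclass
class SelectionRules:
    """Acceptance thresholds for a candidate model."""

    min_fit_percent: float = FIT_THRESHOLD
    min_core_consistency: float = CORE_CONSISTENCY_THRESHOLD
    require_converged: bool = True
    max_member_residual_ratio: float = 3.0
    baseline_cv_threshold: float = 0.2
    baseline_ion_share: float = 0.5
    background_ions: tuple = DEFAULT_BACKGROUND_IONS


@dataclass
class ModelSweepResult:
    interval_label: str
    candidates: list  # (R, fit_percent, core_consistency, sse, converged)
    models: dict  # R -> Parafac2Model
    chosen_r: int | None
    rejection_reasons: dict = field(default_factory=dict)  # R -> list[str]

    @property
    def chosen_model(self) -> Parafac2Model | None:
        return self.models.get(self.chosen_r)


@dataclass
class ComponentRecord:
    """One resolved component: spectrum, apex time, per-member amounts."""

    spectrum: np.ndarray  # dense, on the cube's m/z grid, base peak 999
    mz_axis: np.ndarray
    apex_time: float  # minutes, from the member-averaged elution profile
    amounts: np.ndarray  # K sample loadings
    is_baseline: bool = False
    interval_label: str = ""
    component_index: int = 0

    def as_library_spectrum(self, name: str | None = None) -> LibrarySpectrum:
        nz = np.nonzero(self.spectrum)[0]
        if nz.size == 0:
            raise ValueError("all-zero component spectrum")
        peaks = [(int(self.mz_axis[j]), float(self.spectrum[j])) for j in nz]
        return LibrarySpectrum(
            name or f"{self.interval_label}/component{self.component_index}",
            peaks,
        ).normalize()


def _evaluate_candidate(model: Parafac2Model, cube: IntervalCube,
                        rules: SelectionRules) -> list:
    reasons = []
    if model.fit_percent <= rules.min_fit_percent:
        reasons.append(
            f"fit {model.fit_percent:.2f}% <= {rules.min_fit_percent}%"
        )
    if model.core_consistency <= rules.min_core_consistency:
        reasons.append(
            f"core consistency {model.core_consistency:.2f} <= "
            f"{rules.min_core_consistency}"
        )
    if rules.require_converged and not model.converged:
        reasons.append("ALS did not converge")
    resid = residual_summary(model, cube,
                             imbalance_ratio=rules.max_member_residual_ratio)
    norms = resid["per_member_norm"]
    median = float(np.median(norms))
    if not resid["balanced"]:
        reasons.append(
            f"member residual imbalance: max/median = "
            f"{norms.max() / max(median, 1e-300):.2f} > "
            f"{rules.max_member_residual_ratio}"
        )
    return reasons


def sweep_models(cube: IntervalCube, r_range=range(1, 8),
                 settings: FitSettings | None = None,
                 rules: SelectionRules | None = None) -> ModelSweepResult:
    """Fit one model per candidate R and choose the smallest passing R.

    Fit errors for individual candidates are recorded as rejection reasons
    without aborting the sweep. ``chosen_r`` is None when nothing passes.
    """
    settings = settings or FitSettings()
    rules = rules or SelectionRules()
    candidates, models, rejections = [], {}, {}
    chosen = None
    for r in r_range:
        try:
            model = fit_parafac2(cube, r, settings)
        except Exception as exc:  # record and continue the sweep
            rejections[r] = [f"fit failed: {exc}"]
            candidates.append((r, float("nan"), float("nan"), float("nan"), False))
            continue
        models[r] = model
        candidates.append(
            (r, model.fit_percent, model.core_consistency, model.sse,
             model.converged)
        )
        reasons = _evaluate_candidate(model, cube, rules)
        rejections[r] = reasons
        if chosen is None and not reasons:
            chosen = r
    return ModelSweepResult(
        interval_label=cube.interval.label,
        candidates=candidates,
        models=models,
        chosen_r=chosen,
        rejection_reasons=rejections,
    )


def extract_components(model: Parafac2Model, cube: IntervalCube,
                       rules: SelectionRules | None = None) -> list:
    """Turn a fitted, accepted model into per-component records.

    The spectrum is the spectral loading column rescaled to base peak 999;
    the apex is the scan time of the maximum of the member-averaged elution
    profile; amounts are the sample loadings. Baseline labelling per
    :func:`label_baseline`.
    """
    rules = rules or SelectionRules()
    profiles = model.elution_profiles()
    mean_profile = np.mean(profiles, axis=0)  # I_int x R
    records = []
    for r in range(model.n_components):
        col = model.spectral_loadings[:, r]
        base = col.max()
        spectrum = (
            col * (MAX_RELATIVE_INTENSITY / base) if base > 0 else col.copy()
        )
        apex_idx = int(np.argmax(np.abs(mean_profile[:, r])))
        record = ComponentRecord(
            spectrum=spectrum,
            mz_axis=cube.mz_axis,
            apex_time=float(cube.scan_times[apex_idx]),
            amounts=model.sample_loadings[:, r].copy(),
            interval_label=cube.interval.label,
            component_index=r,
        )
        record.is_baseline = label_baseline(
            record,
            background_ions=rules.background_ions,
            profile=mean_profile[:, r],
            cv_threshold=rules.baseline_cv_threshold,
            ion_share=rules.baseline_ion_share,
        )
        records.append(record)
    return records


def label_baseline(record: ComponentRecord, background_ions=DEFAULT_BACKGROUND_IONS,
                   profile: np.ndarray | None = None,
                   cv_threshold: float = 0.2,
                   ion_share: float = 0.5) -> bool:
    """Flag background/baseline components.

    True iff the elution profile is nearly constant across the interval
    (coefficient of variation < ``cv_threshold``) or at least ``ion_share``
    of the spectrum's intensity lies on configured background ions (e.g.
    siloxanes from column bleed at m/z 207/281/355).
    """
    if profile is not None:
        mean = float(np.mean(np.abs(profile)))
        if mean > 0:
            cv = float(np.std(profile)) / mean
            if cv < cv_threshold:
                return True
    total = float(record.spectrum.sum())
    if total > 0:
        bg = set(int(m) for m in background_ions)
        on_bg = sum(
            float(record.spectrum[j])
            for j, mz in enumerate(record.mz_axis)
            if int(mz) in bg
        )
        if on_bg / total >= ion_share:
            return True
    return False
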