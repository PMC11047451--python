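"""Lead-field numerical quality control and the automatic correction loop.

The quality index is the Pearson correlation between a tested lead field and
the boundary-free homogeneous baseline, computed in two modes: source-wide
(per sensor, across the row) and sensor-wide (per source, down the column).
Sensors correlating below 0.7 and sources below 0.33 (strict "below": the
boundary passes) flag the lead field as artifactual.  Sources sitting closer
to the inner-skull surface than a minimum distance are flagged geometrically,
and corrected by warping the inner skull locally outward, after which the
lead field is recomputed -- the loop of flag -> correct -> recompute runs
until the model passes or is declared incorrigible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .forward import (
    HeadModel,
    LeadField,
    SensorArray,
    SourceSpace,
    apply_orientation_constraint,
    homogeneous_leadfield_eeg,
)
from .mesh import TriMesh, surface_surface_distances, vertex_normals, warp_surface_outward


@dataclass
class QCThresholds:
    sensor_corr_threshold: float = 0.7
    source_corr_threshold: float = 0.33
    min_distance_m: float = 0.002
    max_iterations: int = 3
    flag_mode: str = "any"  # flag when ANY mode violates, or only when ALL do

    def __post_init__(self) -> None:
        for v in (self.sensor_corr_threshold, self.source_corr_threshold):
            if not (0 < v <= 1):
                raise ValueError("correlation thresholds must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.flag_mode not in ("any", "all"):
            raise ValueError("flag_mode must be 'any' or 'all'")


@dataclass
class QCResult:
    per_sensor_corr: np.ndarray | None = None
    per_source_corr: np.ndarray | None = None
    fit: tuple | None = None  # (slope, intercept, r2)
    sensor_flags: np.ndarray | None = None
    source_flags: np.ndarray | None = None
    distance_flags: np.ndarray | None = None
    undefined_rows: np.ndarray | None = None
    undefined_cols: np.ndarray | None = None
    status: str = "pass"  # {pass, flagged, corrected, incorrigible}
    history: list = field(default_factory=list)
    violated: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "per_sensor_corr": arr(self.per_sensor_corr),
            "per_source_corr": arr(self.per_source_corr),
            "fit": None if self.fit is None else list(self.fit),
            "sensor_flags": arr(self.sensor_flags),
            "source_flags": arr(self.source_flags),
            "distance_flags": arr(self.distance_flags),
            "status": self.status,
            "history": self.history,
            "violated": self.violated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCResult":
        def arr(a, dtype=float):
            return None if a is None else np.asarray(a, dtype=dtype)

        return cls(
            per_sensor_corr=arr(d["per_sensor_corr"]),
            per_source_corr=arr(d["per_source_corr"]),
            fit=None if d["fit"] is None else tuple(d["fit"]),
            sensor_flags=arr(d["sensor_flags"], bool),
            source_flags=arr(d["source_flags"], bool),
            distance_flags=arr(d["distance_flags"], bool),
            status=d["status"],
            history=d["history"],
            violated=d["violated"],
        )


def _rowwise_pearson(A: np.ndarray, B: np.ndarray):
    """Pearson r of matching rows; returns (r, undefined_mask)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    undef = (na == 0) | (nb == 0)
    denom = np.where(undef, 1.0, na * nb)
    r = np.einsum("ij,ij->i", Ac, Bc) / denom
    r[undef] = np.nan
    return np.clip(r, -1.0, 1.0), undef


def leadfield_correlations(L_test: LeadField, L_hom: LeadField):
    """Source-wide (per sensor) and sensor-wide (per source) Pearson
    correlations between a tested and the homogeneous lead field."""
    A, B = L_test.matrix, L_hom.matrix
    if A.shape != B.shape:
        raise ValueError(f"lead field shapes differ: {A.shape} vs {B.shape}")
    if L_test.mode != "constrained" or L_hom.mode != "constrained":
        raise ValueError("correlations require orientation-constrained lead fields")
    per_sensor, undef_rows = _rowwise_pearson(A, B)
    per_source, undef_cols = _rowwise_pearson(A.T, B.T)
    return per_sensor, per_source, undef_rows, undef_cols


def leadfield_linear_fit(L_test: LeadField, L_hom: LeadField):
    """OLS of the vectorized tested lead field on the homogeneous one.

    Returns (slope, intercept, R^2)."""
    x = L_hom.matrix.ravel()
    y = L_test.matrix.ravel()
    if np.ptp(x) == 0:
        raise ValueError("homogeneous lead field is constant; fit undefined")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
    return slope, intercept, r2


def flag_leadfield(qc: QCResult, thr: QCThresholds) -> QCResult:
    """Apply the strict-below thresholds; undefined correlations flag too."""
    ps, pc = qc.per_sensor_corr, qc.per_source_corr
    sflag = (ps < thr.sensor_corr_threshold) | np.asarray(qc.undefined_rows, bool)
    cflag = (pc < thr.source_corr_threshold) | np.asarray(qc.undefined_cols, bool)
    qc.sensor_flags = sflag
    qc.source_flags = cflag
    qc.violated = []
    if sflag.any():
        qc.violated.append(
            {"threshold": "sensor_corr_threshold", "value": thr.sensor_corr_threshold,
             "n_flagged": int(sflag.sum())}
        )
    if cflag.any():
        qc.violated.append(
            {"threshold": "source_corr_threshold", "value": thr.source_corr_threshold,
             "n_flagged": int(cflag.sum())}
        )
    corr_flagged = (
        sflag.any() or cflag.any() if thr.flag_mode == "any" else sflag.any() and cflag.any()
    )
    dist_flagged = qc.distance_flags is not None and np.asarray(qc.distance_flags).any()
    qc.status = "flagged" if (corr_flagged or dist_flagged) else "pass"
    return qc


def distance_flag_sources(src: SourceSpace, inner_skull: TriMesh, min_distance_m: float):
    """Flag sources closer than ``min_distance_m`` to the inner skull."""
    dist, flags = surface_surface_distances(src.positions, inner_skull, min_distance_m)
    return dist, flags


def evaluate_leadfield(
    L_test: LeadField,
    head: HeadModel,
    src: SourceSpace,
    sensors: SensorArray,
    thr: QCThresholds,
    normals: np.ndarray | None = None,
) -> QCResult:
    """One QC pass: correlations against the homogeneous baseline, linear
    fit, correlation and distance flags."""
    if normals is None:
        normals = src.orientations
    L_hom = homogeneous_leadfield_eeg(
        SourceSpace(src.positions), sensors, sigma=head.conductivities[0]
    )
    L_hom = apply_orientation_constraint(L_hom, normals)
    if L_test.mode == "free":
        L_test = apply_orientation_constraint(L_test, normals)
    ps, pc, ur, uc = leadfield_correlations(L_test, L_hom)
    fit = leadfield_linear_fit(L_test, L_hom)
    dist, dflags = distance_flag_sources(src, head.inner_skull, thr.min_distance_m)
    qc = QCResult(
        per_sensor_corr=ps, per_source_corr=pc, fit=fit,
        distance_flags=dflags, undefined_rows=ur, undefined_cols=uc,
    )
    qc = flag_leadfield(qc, thr)
    if dflags.any():
        qc.violated.append(
            {"threshold": "min_distance_m", "value": thr.min_distance_m,
             "n_flagged": int(dflags.sum())}
        )
    qc._distances = dist  # stashed for the control loop
    return qc


def qc_control_loop(
    head: HeadModel,
    src: SourceSpace,
    sensors: SensorArray,
    lf_provider,
    thr: QCThresholds,
    smoothing_radius_m: float = 0.02,
):
    """Automatic flag -> correct -> recompute loop.

    ``lf_provider(head, src, sensors) -> LeadField`` computes the tested lead
    field from the current geometry.  Distance violations are corrected by
    warping the inner skull outward; the loop stops at the first clean pass or
    after ``max_iterations``, in which case the result is incorrigible.
    """
    history = []
    status = "pass"
    corrected = False
    qc = None
    for it in range(thr.max_iterations):
        try:
            L_test = lf_provider(head, src, sensors)
        except Exception as exc:
            raise RuntimeError(f"lead-field provider failed at iteration {it}") from exc
        qc = evaluate_leadfield(L_test, head, src, sensors, thr)
        entry = {
            "iteration": it,
            "status": qc.status,
            "min_sensor_corr": float(np.nanmin(qc.per_sensor_corr)),
            "min_source_corr": float(np.nanmin(qc.per_source_corr)),
            "n_distance_flags": int(np.sum(qc.distance_flags)),
            "violated": qc.violated,
        }
        history.append(entry)
        if qc.status == "pass":
            status = "corrected" if corrected else "pass"
            break
        if np.any(qc.distance_flags) and it < thr.max_iterations - 1:
            offending = src.positions[np.asarray(qc.distance_flags)]
            warped, corrigible = warp_surface_outward(
                head.inner_skull, offending, thr.min_distance_m,
                smoothing_radius_m, outer_limit=head.outer_skull,
            )
            head = HeadModel(
                cortex=head.cortex, inner_skull=warped, outer_skull=head.outer_skull,
                scalp=head.scalp, conductivities=head.conductivities,
                model_type=head.model_type, provenance=head.provenance,
            )
            corrected = True
            entry["correction"] = "warp_inner_skull_outward"
            if not corrigible:
                status = "incorrigible"
                break
        else:
            status = "incorrigible"
            break
    else:
        status = "incorrigible"
    qc.history = history
    qc.status = status if status != "pass" or qc.status == "pass" else qc.status
    if status == "incorrigible":
        qc.status = "incorrigible"
    elif status == "corrected":
        qc.status = "corrected"
    return head, L_test, qc


def template_fallback(template: str | None = None, n_sources: int = 200):
    """Substitute a template head/source model for an incorrigible
    individual model; provenance is recorded as 'template'.

    ``template`` may be a directory holding cortex/inner_skull/outer_skull/
    scalp surfaces (``<name>.off``); with ``None`` the packaged spherical
    template is generated.  Missing paths raise.
    """
    if template is None:
        from .synth import make_nested_head, make_source_cap

        head = make_nested_head(subdivisions=4)
        pos, normals, _, _ = make_source_cap(head.cortex, n_sources)
    else:
        import os as _os

        from .io import load_surface

        surfaces = {}
        for name in ("cortex", "inner_skull", "outer_skull", "scalp"):
            path = _os.path.join(template, f"{name}.off")
            if not _os.path.exists(path):
                raise FileNotFoundError(f"template surface missing: {path}")
            surfaces[name] = load_surface(path)
        head = HeadModel(**surfaces)
        pos = head.cortex.vertices
        normals = pos / np.linalg.norm(pos, axis=1)[:, None]
    head = HeadModel(
        cortex=head.cortex, inner_skull=head.inner_skull,
        outer_skull=head.outer_skull, scalp=head.scalp,
        conductivities=head.conductivities, model_type=head.model_type,
        provenance="template",
    )
    return head, SourceSpace(pos, orientations=normals, mode="constrained")


def generate_qc_report(qc: QCResult, out_dir: str, make_figures: bool = True) -> dict:
    """Write the QC metrics as JSON plus diagnostic figures.

    Figures: per-sensor and per-source correlation bars with thresholds, the
    tested-vs-homogeneous scatter is summarized by its fit line parameters.
    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "qc_report.json")
    with open(json_path, "w") as fh:
        json.dump({"version": 1, "qc": qc.to_dict()}, fh, indent=1)
    paths = {"json": json_path}
    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 3.5))
        axes[0].bar(np.arange(len(qc.per_sensor_corr)), qc.per_sensor_corr, color="tab:blue")
        axes[0].set_title("source-wide correlation per sensor")
        axes[0].set_ylim(-0.1, 1.05)
        axes[1].plot(np.sort(qc.per_source_corr), color="tab:green")
        axes[1].set_title("sensor-wide correlation per source (sorted)")
        for ax in axes:
            ax.set_ylabel("Pearson r")
        fig.tight_layout()
        fig_path = os.path.join(out_dir, "qc_correlations.png")
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        paths["figure"] = fig_path
    return paths


def load_qc_report(path: str) -> QCResult:
    with open(path) as fh:
        return QCResult.from_dict(json.load(fh)["qc"])
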