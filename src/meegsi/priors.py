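"""Geometrical and structural priors as lead-field standardizations.

Each prior is realized as a transformation of the design matrix (the lead
field) applied before inverse solving, with the matching de-standardization
applied to the estimate afterwards:

* rotational invariance -- project the free-orientation lead field onto the
  surface normals, solve a scalar problem, lift the solution back to a 3x3
  tensor field per source pair and re-project onto the per-source direction
  of maximum spectral amplitude;
* curvature depth compensation -- divide each source column by a piecewise
  linear function of the mean curvature (separate slope/intercept for gyri,
  curvature >= 0, and sulci, curvature < 0);
* graph-Laplacian smoothing -- right-multiply the lead field by the (deformed)
  Laplacian pseudoinverse;
* parcellation grouping -- tie the per-source scale hyperparameters of the
  sparse Bayesian solver within labeled groups.

Standardizations compose in the order curvature -> laplacian -> rotational
invariance (column scalings, then smoothing, then orientation reduction), and
every step records an inverse closure so estimates can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField, apply_orientation_constraint
from .mesh import GraphLaplacian, laplacian_pseudoinverse_factor


@dataclass
class StandardizedLeadField:
    """A lead field with recorded forward transforms and inverse closures."""

    L_std: LeadField
    transforms: list = field(default_factory=list)  # names, in application order
    #: maps source-domain estimates of the standardized problem back to the
    #: original parameterization; one callable per transform, applied in
    #: reverse order by :meth:`destandardize_coefficients`
    inverse_closures: list = field(default_factory=list)

    def destandardize_coefficients(self, x: np.ndarray) -> np.ndarray:
        for f in reversed(self.inverse_closures):
            x = f(x)
        return x


# ---------------------------------------------------------------------------
# prior 1: rotational invariance


def rotational_invariance_standardize(L_free: LeadField, normals: np.ndarray) -> StandardizedLeadField:
    """Standardize a free-orientation lead field to a scalar problem.

    The lead field is projected onto the surface normals; machinery (normals)
    is kept so the scalar estimates can be lifted back to vector fields.
    """
    normals = np.asarray(normals, dtype=np.float64)
    nn = np.linalg.norm(normals, axis=1)
    if np.any(nn < 1e-12):
        raise ValueError("zero normal vector")
    if np.any(np.abs(nn - 1.0) > 1e-8):
        raise ValueError("normals must be unit vectors")
    L_n = apply_orientation_constraint(L_free, normals)
    std = StandardizedLeadField(L_std=L_n)
    std.transforms.append("rotational_invariance")
    std.normals = normals  # type: ignore[attr-defined]
    std.inverse_closures.append(lambda x: x)  # scalar estimates stay scalar here;
    # the tensor lift is performed by rotational_invariance_destandardize
    return std


def rotational_invariance_destandardize(S_scalar: np.ndarray, normals: np.ndarray):
    """Lift a scalar source cross-spectrum back to the vector-field picture.

    Returns ``(S_3x3, max_dirs, S_projected)``:

    * ``S_3x3``: per source pair the 3x3 complex cross-spectral block
      n_i S_ij n_j^T,
    * ``max_dirs``: per source the real unit direction of maximum spectral
      amplitude (principal eigenvector of the source's own 3x3 spectrum),
    * ``S_projected``: the cross-spectrum re-projected onto those directions.
    """
    S_scalar = np.asarray(S_scalar)
    if np.linalg.norm(S_scalar - S_scalar.conj().T) > 1e-8 * max(np.linalg.norm(S_scalar), 1e-300):
        raise ValueError("input cross-spectrum is not Hermitian")
    normals = np.asarray(normals, dtype=np.float64)
    S = S_scalar.shape[0]
    max_dirs = np.zeros((S, 3))
    for i in range(S):
        block = S_scalar[i, i].real * np.outer(normals[i], normals[i])
        w, V = np.linalg.eigh(block)
        d = V[:, -1]
        # deterministic sign: positive on its largest component
        k = np.argmax(np.abs(d))
        max_dirs[i] = d * np.sign(d[k]) if d[k] != 0 else d
    align = np.einsum("ik,ik->i", max_dirs, normals)  # n_i . d_i
    S_projected = S_scalar * np.einsum("i,j->ij", align, align)

    def block_fn(i: int, j: int) -> np.ndarray:
        return S_scalar[i, j] * np.outer(normals[i], normals[j])

    return block_fn, max_dirs, S_projected


# ---------------------------------------------------------------------------
# prior 2: curvature depth compensation


def curvature_compensation_weights(
    H: np.ndarray,
    slope_gyri: float = 0.5,
    intercept_gyri: float = 1.0,
    slope_sulci: float = 0.5,
    intercept_sulci: float = 1.0,
) -> np.ndarray:
    """Piecewise-linear curvature weights, gyral branch for H >= 0.

    w_i = intercept_g + slope_g * H_i  (H_i >= 0)
        = intercept_s + slope_s * H_i  (H_i < 0)

    All weights must come out strictly positive.
    """
    H = np.asarray(H, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValueError("curvature contains non-finite values")
    w = np.where(H >= 0, intercept_gyri + slope_gyri * H, intercept_sulci + slope_sulci * H)
    if np.any(w <= 0):
        raise ValueError("curvature weights must be strictly positive; adjust slope/intercept")
    return w


def curvature_standardize(L: LeadField, weights: np.ndarray) -> StandardizedLeadField:
    """Divide each source column by its curvature weight (constrained mode)."""
    if L.mode != "constrained":
        raise ValueError("curvature standardization expects a constrained lead field")
    weights = np.asarray(weights, dtype=np.float64)
    M = L.matrix / weights[None, :]
    out = LeadField(M, mode="constrained", units=L.units, reference=L.reference,
                    provenance=L.provenance, sensor_labels=list(L.sensor_labels))
    std = StandardizedLeadField(L_std=out)
    std.transforms.append("curvature")
    std.inverse_closures.append(lambda x, w=weights: x / w[:, None] if x.ndim == 2 else x / w)
    return std


# ---------------------------------------------------------------------------
# prior 3: graph Laplacian smoothing


def laplacian_standardize(L: LeadField, lap: GraphLaplacian) -> StandardizedLeadField:
    """Right-multiply the lead field by the Laplacian pseudoinverse factor M;
    estimates x_std of the standardized problem map back as x = M x_std."""
    if L.mode != "constrained":
        raise ValueError("laplacian standardization expects a constrained lead field")
    M = laplacian_pseudoinverse_factor(lap)
    if M.shape[0] != L.matrix.shape[1]:
        raise ValueError("Laplacian size does not match source count")
    out = LeadField(L.matrix @ M, mode="constrained", units=L.units, reference=L.reference,
                    provenance=L.provenance, sensor_labels=list(L.sensor_labels))
    std = StandardizedLeadField(L_std=out)
    std.transforms.append("laplacian")
    std.factor = M  # type: ignore[attr-defined]
    std.inverse_closures.append(lambda x, M=M: M @ x)
    return std


# ---------------------------------------------------------------------------
# prior 4: parcellation groups


def parcellation_groups(labels) -> dict:
    """Group index structure mapping label -> member source indices.

    Every source must carry a label; empty groups are impossible by
    construction, and the result feeds the grouped scale hyperparameters of
    the sparse Bayesian solver.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    if any(l is None for l in labels.tolist()) or (
        labels.dtype.kind == "f" and np.any(np.isnan(labels))
    ):
        raise ValueError("every source needs a parcellation label")
    groups: dict = {}
    for i, l in enumerate(labels.tolist()):
        groups.setdefault(l, []).append(i)
    return {k: np.asarray(v, dtype=np.int64) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# composition


def compose_standardizations(stds: list) -> StandardizedLeadField:
    """Chain standardizations applied in sequence (first applied first)."""
    if not stds:
        raise ValueError("nothing to compose")
    out = StandardizedLeadField(L_std=stds[-1].L_std)
    for s in stds:
        out.transforms += s.transforms
        out.inverse_closures += s.inverse_closures
    return out
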