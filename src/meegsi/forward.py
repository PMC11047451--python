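"""Analytic forward models and sensor registration.

Three lead-field families are provided:

* the homogeneous (infinite-medium) dipole solution -- the boundary-free
  baseline every quality-control correlation is computed against,
* the three-shell concentric-spheres EEG model (truncated Legendre series),
  a realistic-enough stand-in for boundary-element solutions, and
* the spherical-conductor MEG magnetometer model (Sarvas closed form).

All coordinates are SI meters; EEG lead fields are in V/(A*m), MEG in
T/(A*m).  Average reference (zero column mean over sensors) is applied to
EEG lead fields by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, lpmv

from .mesh import TriMesh

MU0 = 4e-7 * np.pi


@dataclass
class SensorArray:
    """A labeled set of sensors.

    EEG sensors are points on (or projected to) the scalp; MEG magnetometers
    additionally carry a unit orientation along which the field component is
    measured.
    """

    labels: list
    positions: np.ndarray  # (N, 3) meters
    kind: str = "eeg"  # {"eeg", "meg_magnetometer"}
    orientations: np.ndarray | None = None  # (N, 3), MEG only
    reference: str = "average"  # {"average", "none"}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels/positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sensor labels")
        if self.kind not in ("eeg", "meg_magnetometer"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if self.kind == "meg_magnetometer":
            if self.orientations is None:
                raise ValueError("MEG magnetometers require orientations")
            self.orientations = np.asarray(self.orientations, dtype=np.float64)
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-8):
                raise ValueError("MEG orientations must be unit norm")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)


@dataclass
class SourceSpace:
    """Dipolar source locations with free or normal-constrained orientation."""

    positions: np.ndarray  # (S, 3) meters
    orientations: np.ndarray | None = None  # (S, 3) unit normals if constrained
    mode: str = "free"  # {"free", "constrained"}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.mode not in ("free", "constrained"):
            raise ValueError(f"unknown orientation mode {self.mode!r}")
        if self.mode == "constrained":
            if self.orientations is None:
                raise ValueError("constrained mode requires orientations")
            self.orientations = np.asarray(self.orientations, dtype=np.float64)

    @property
    def n_sources(self) -> int:
        return len(self.positions)


@dataclass
class HeadModel:
    """Nested conductor geometry: cortex < inner skull < outer skull < scalp."""

    cortex: TriMesh
    inner_skull: TriMesh
    outer_skull: TriMesh
    scalp: TriMesh
    conductivities: tuple = (0.33, 0.0042, 0.33)  # brain, skull, scalp (S/m)
    model_type: str = "three_shell_sphere"
    provenance: str = "individual"  # {"individual", "template"}

    def surfaces(self):
        return {
            "cortex": self.cortex,
            "inner_skull": self.inner_skull,
            "outer_skull": self.outer_skull,
            "scalp": self.scalp,
        }


@dataclass
class LeadField:
    """Dense real lead-field matrix, sensors in rows.

    ``matrix`` is (N, S) in constrained mode or (N, 3S) in free mode with the
    three Cartesian moment components of source i in columns 3i..3i+2.
    """

    matrix: np.ndarray
    mode: str = "constrained"  # {"free", "constrained"}
    units: str = "V/(A*m)"
    reference: str = "average"
    provenance: str = "homogeneous"  # {"homogeneous", "sphere", "imported"}
    sensor_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field contains non-finite entries")
        if self.mode == "free" and self.matrix.shape[1] % 3 != 0:
            raise ValueError("free-orientation lead field needs 3 columns per source")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        c = self.matrix.shape[1]
        return c // 3 if self.mode == "free" else c


def _average_reference(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def project_sensors_to_scalp(sensors: SensorArray, scalp: TriMesh) -> SensorArray:
    """Replace each EEG sensor position by its nearest point on the scalp."""
    if sensors.kind != "eeg":
        raise ValueError("scalp projection applies to EEG sensors only")
    from .mesh import closest_point_on_surface

    closest, _ = closest_point_on_surface(sensors.positions, scalp)
    return SensorArray(
        labels=list(sensors.labels),
        positions=np.asarray(closest),
        kind="eeg",
        reference=sensors.reference,
    )


def landmark_rigid_align(
    sensors: SensorArray, sensor_landmarks: dict, head_landmarks: dict
) -> SensorArray:
    """Rigidly align a sensor array to the head via matched labeled landmarks.

    Least-squares rotation + translation (Kabsch); requires at least three
    non-collinear landmark pairs.
    """
    common = [k for k in sensor_landmarks if k in head_landmarks]
    if len(common) < 3:
        raise ValueError("need at least 3 matched landmarks")
    A = np.asarray([sensor_landmarks[k] for k in common], dtype=np.float64)
    B = np.asarray([head_landmarks[k] for k in common], dtype=np.float64)
    Ac, Bc = A - A.mean(axis=0), B - B.mean(axis=0)
    if np.linalg.matrix_rank(Ac, tol=1e-12 * max(1.0, np.abs(Ac).max())) < 2:
        raise ValueError("landmarks are collinear")
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = B.mean(axis=0) - R @ A.mean(axis=0)
    return SensorArray(
        labels=list(sensors.labels),
        positions=sensors.positions @ R.T + t,
        kind=sensors.kind,
        orientations=None if sensors.orientations is None else sensors.orientations @ R.T,
        reference=sensors.reference,
    )


def homogeneous_potential(r: np.ndarray, r0: np.ndarray, q: np.ndarray, sigma: float) -> float:
    """Infinite-medium dipole potential V(r) = q.(r-r0) / (4 pi sigma |r-r0|^3)."""
    d = np.asarray(r, float) - np.asarray(r0, float)
    nd = np.linalg.norm(d)
    return float(np.dot(q, d) / (4.0 * np.pi * sigma * nd**3))


def homogeneous_leadfield_eeg(
    src: SourceSpace, sensors: SensorArray, sigma: float = 0.33, reference: str | None = None
) -> LeadField:
    """Boundary-free (infinite homogeneous medium) EEG lead field.

    This is the analytic baseline solution of the Poisson equation with no
    boundaries; the mean-field conductivity ``sigma`` only scales the matrix,
    so quality-control correlations are independent of its value.
    """
    d = sensors.positions[:, None, :] - src.positions[None, :, :]  # (N, S, 3)
    nd = np.linalg.norm(d, axis=2)
    if np.any(nd < 1e-6):
        raise ValueError("a sensor coincides with a source")
    K = d / (4.0 * np.pi * sigma * nd**3)[:, :, None]  # (N, S, 3)
    L = K.reshape(K.shape[0], -1)
    lf = LeadField(L, mode="free", provenance="homogeneous", sensor_labels=list(sensors.labels))
    ref = sensors.reference if reference is None else reference
    if ref == "average":
        lf.matrix = _average_reference(lf.matrix)
        lf.reference = "average"
    else:
        lf.reference = "none"
    if src.mode == "constrained":
        lf = apply_orientation_constraint(lf, src.orientations)
    return lf


def _sphere_series_coeffs(radii, sigmas, n_terms):
    """Per-harmonic surface transfer coefficients for concentric shells.

    For each degree n, solves the radial two-point boundary problem for a
    source term b^(n-1) r^-(n+1) in the innermost compartment (conductivity
    sigmas[0]) with sigma*dV/dr = 0 at the outermost radius.  Returns the
    (A_out, B_out) pair of the outermost shell such that the surface radial
    factor is A_out*R^n + B_out*R^-(n+1) for a unit source coefficient.
    """
    radii = np.asarray(radii, dtype=np.float64)
    sigmas = np.asarray(sigmas, dtype=np.float64)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly ascending")
    if np.any(sigmas <= 0):
        raise ValueError("conductivities must be positive")
    Lsh = len(radii)
    out = np.zeros((n_terms + 1, 2))
    for n in range(1, n_terms + 1):
        # unknowns: A_1, then (A_l, B_l) for l = 2..Lsh  -> 2*Lsh - 1
        nun = 2 * Lsh - 1
        M = np.zeros((nun, nun))
        rhs = np.zeros(nun)

        def a_idx(l):  # A coefficient column of shell l (0-based shells)
            return 0 if l == 0 else 1 + 2 * (l - 1)

        def b_idx(l):
            assert l >= 1
            return 2 + 2 * (l - 1)

        row = 0
        for l in range(Lsh - 1):
            r = radii[l]
            # potential continuity: A_l r^n + B_l r^-(n+1) = A_{l+1} r^n + B_{l+1} r^-(n+1)
            M[row, a_idx(l)] += r**n
            if l >= 1:
                M[row, b_idx(l)] += r ** -(n + 1)
            else:
                rhs[row] -= r ** -(n + 1)  # source B_1 = 1
            M[row, a_idx(l + 1)] -= r**n
            M[row, b_idx(l + 1)] -= r ** -(n + 1)
            row += 1
            # current continuity: sigma_l (n A_l r^(n-1) - (n+1) B_l r^-(n+2)) = ...
            M[row, a_idx(l)] += sigmas[l] * n * r ** (n - 1)
            if l >= 1:
                M[row, b_idx(l)] += -sigmas[l] * (n + 1) * r ** -(n + 2)
            else:
                rhs[row] -= -sigmas[l] * (n + 1) * r ** -(n + 2)
            M[row, a_idx(l + 1)] -= sigmas[l + 1] * n * r ** (n - 1)
            M[row, b_idx(l + 1)] -= -sigmas[l + 1] * (n + 1) * r ** -(n + 2)
            row += 1
        # outer boundary: no current into air
        R = radii[-1]
        lo = Lsh - 1
        M[row, a_idx(lo)] += n * R ** (n - 1)
        if lo >= 1:
            M[row, b_idx(lo)] += -(n + 1) * R ** -(n + 2)
        else:
            rhs[row] -= -(n + 1) * R ** -(n + 2)
        sol = np.linalg.solve(M, rhs)
        A_out = sol[a_idx(Lsh - 1)]
        B_out = 1.0 if Lsh == 1 else sol[b_idx(Lsh - 1)]
        out[n] = (A_out, B_out)
    return out


def sphere_series_potentials(
    src_pos, sensor_pos, radii, sigmas, n_terms=60
):
    """Surface potentials of unit Cartesian dipoles inside concentric
    conductive spheres (Legendre series).

    Returns a (N, S, 3) array: potential at each sensor for a unit dipole
    moment along each Cartesian axis at each source.
    """
    src_pos = np.atleast_2d(np.asarray(src_pos, dtype=np.float64))
    sensor_pos = np.atleast_2d(np.asarray(sensor_pos, dtype=np.float64))
    radii = np.asarray(radii, dtype=np.float64)
    R = radii[-1]
    b = np.linalg.norm(src_pos, axis=1)
    if np.any(b >= radii[0]):
        raise ValueError("sources must lie strictly inside the innermost radius")
    # project sensors to the outermost radius
    sn = np.linalg.norm(sensor_pos, axis=1)
    sensor_pos = sensor_pos * (R / sn)[:, None]

    # nondimensionalize radii by R so the per-degree powers stay bounded
    coeffs = _sphere_series_coeffs(radii / R, sigmas, n_terms)  # (n_terms+1, 2)
    ns = np.arange(1, n_terms + 1)
    # radial surface factor per degree for unit source coefficient (scaled
    # radius 1 at the surface); the 1/R^2 dimension is restored below
    surf = coeffs[1:, 0] + coeffs[1:, 1]
    b = b / R

    N, S = len(sensor_pos), len(src_pos)
    out = np.zeros((N, S, 3))
    sigma1 = sigmas[0]
    rhat = sensor_pos / R
    for j in range(S):
        bj = b[j]
        if bj < 1e-12:
            er = np.array([0.0, 0.0, 1.0])
            bj = 0.0
        else:
            er = src_pos[j] / np.linalg.norm(src_pos[j])
        cosg = rhat @ er  # (N,)
        cosg = np.clip(cosg, -1.0, 1.0)
        # tangential unit vector from the dipole axis toward each sensor
        tvec = rhat - cosg[:, None] * er[None, :]
        tnorm = np.linalg.norm(tvec, axis=1)
        safe = tnorm > 1e-12
        that = np.zeros_like(tvec)
        that[safe] = tvec[safe] / tnorm[safe, None]

        # b^(n-1): with the 0^0 = 1 convention a central dipole keeps n = 1
        with np.errstate(divide="ignore"):
            bpow = np.where(ns == 1, 1.0, bj ** (ns - 1))
        fac = bpow * surf / (4.0 * np.pi * sigma1 * R**2)  # (n_terms,)

        Pn = np.stack([eval_legendre(n, cosg) for n in ns], axis=1)  # (N, n_terms)
        Pn1 = np.stack([lpmv(1, n, cosg) for n in ns], axis=1)
        # radial moment component: sum fac * n * P_n
        rad = Pn @ (fac * ns)
        # tangential: sum fac * (-P_n^1)   [lpmv includes the (-1)^m factor]
        tang = Pn1 @ (-fac)
        # assemble Cartesian columns: q = q_r er + q_t that_component
        for ax in range(3):
            q = np.zeros(3)
            q[ax] = 1.0
            qr = float(q @ er)
            qt = that @ q  # (N,) component of q along each sensor's tangent dir
            out[:, j, ax] = qr * rad + qt * tang
    return out


def three_shell_sphere_leadfield_eeg(
    src: SourceSpace,
    sensors: SensorArray,
    radii=(0.079, 0.082, 0.088),
    sigmas=(0.33, 0.0042, 0.33),
    n_terms: int = 60,
    reference: str | None = None,
) -> LeadField:
    """Three-shell concentric-spheres EEG lead field (Legendre series).

    ``radii`` are the brain/inner-skull, outer-skull and scalp shell outer
    radii; sensors are projected radially to the outermost radius.
    """
    if n_terms < 20:
        raise ValueError("n_terms must be >= 20")
    pot = sphere_series_potentials(src.positions, sensors.positions, radii, sigmas, n_terms)
    L = pot.reshape(pot.shape[0], -1)
    lf = LeadField(L, mode="free", provenance="sphere", sensor_labels=list(sensors.labels))
    ref = sensors.reference if reference is None else reference
    if ref == "average":
        lf.matrix = _average_reference(lf.matrix)
        lf.reference = "average"
    else:
        lf.reference = "none"
    if src.mode == "constrained":
        lf = apply_orientation_constraint(lf, src.orientations)
    return lf


def sphere_leadfield_meg(
    src: SourceSpace, sensors: SensorArray, sphere_center=(0.0, 0.0, 0.0)
) -> LeadField:
    """Spherical-conductor magnetometer lead field (Sarvas closed form).

    The solution is independent of the conductivity profile of the sphere;
    purely radial dipoles are magnetically silent.
    """
    if sensors.kind != "meg_magnetometer":
        raise ValueError("MEG lead field requires magnetometer sensors")
    c = np.asarray(sphere_center, dtype=np.float64)
    rs = sensors.positions - c  # (N, 3)
    r0 = src.positions - c  # (S, 3)
    N, S = len(rs), len(r0)
    L = np.zeros((N, 3 * S))
    for i in range(N):
        r = rs[i]
        rn = np.linalg.norm(r)
        for j in range(S):
            a_vec = r - r0[j]
            a = np.linalg.norm(a_vec)
            if a < 1e-9:
                raise ValueError("sensor coincides with a source")
            ar = float(a_vec @ r)
            F = a * (rn * a + rn**2 - float(r0[j] @ r))
            gradF = (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn) * r - (
                a + 2.0 * rn + ar / a
            ) * r0[j]
            for ax in range(3):
                q = np.zeros(3)
                q[ax] = 1.0
                qxr0 = np.cross(q, r0[j])
                B = MU0 / (4.0 * np.pi * F**2) * (F * qxr0 - float(qxr0 @ r) * gradF)
                L[i, 3 * j + ax] = float(B @ sensors.orientations[i])
    return LeadField(
        L, mode="free", units="T/(A*m)", reference="none", provenance="sphere",
        sensor_labels=list(sensors.labels),
    )


def apply_orientation_constraint(lf: LeadField, normals: np.ndarray) -> LeadField:
    """Project a free-orientation lead field onto per-source unit normals."""
    if lf.mode != "free":
        raise ValueError("lead field is already orientation-constrained")
    normals = np.asarray(normals, dtype=np.float64)
    if np.any(np.abs(np.linalg.norm(normals, axis=1) - 1.0) > 1e-8):
        raise ValueError("normals must be unit vectors")
    S = lf.n_sources
    if normals.shape != (S, 3):
        raise ValueError("normals shape mismatch")
    M = lf.matrix.reshape(lf.n_sensors, S, 3)
    out = np.einsum("nsk,sk->ns", M, normals)
    return LeadField(
        out, mode="constrained", units=lf.units, reference=lf.reference,
        provenance=lf.provenance, sensor_labels=list(lf.sensor_labels),
    )
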