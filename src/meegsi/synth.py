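"""Deterministic synthetic fixtures: spherical head models, 10-20 sensor
layouts, oscillatory source networks with exactly known cross-spectra, paired
MEG/EEG spectra tensors, and artifact injectors.

Everything here is a pure function of its arguments and a seed.  Sources are
simulated by spectral synthesis -- complex Gaussian Fourier coefficients drawn
per frequency bin with a prescribed cross-spectral density and inverse
transformed to real stationary series -- so the theoretical cross-spectral
tensor is exact rather than asymptotic.  The generators deliberately emulate
the known failure modes of real pipelines (dented inner-skull surfaces, sensor
misalignment, noise-corrupted lead-field columns) so that the quality-control
loop can be exercised end to end without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import HeadModel, LeadField, SensorArray
from .mesh import TriMesh
from .spectral import TimeSeriesData


# ---------------------------------------------------------------------------
# geometry fixtures


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to a sphere.

    Vertex count is 10*4**s + 2.
    """
    if not (0 <= subdivisions <= 6):
        raise ValueError("subdivisions must be in [0, 6]")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        edge_mid: dict = {}
        new_faces = []
        vlist = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key in edge_mid:
                return edge_mid[key]
            m = vlist[a] + vlist[b]
            m = m / np.linalg.norm(m)
            vlist.append(m)
            edge_mid[key] = len(vlist) - 1
            return edge_mid[key]

        for f in faces:
            a, b, c = (int(x) for x in f)
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriMesh(verts * radius, faces)


def make_nested_head(
    radii=(0.079, 0.082, 0.088, 0.092),
    subdivisions: int = 3,
    conductivities=(0.33, 0.0042, 0.33),
) -> HeadModel:
    """Four nested icospheres: cortex, inner skull, outer skull, scalp."""
    radii = tuple(float(r) for r in radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly ascending")
    cortex, inner, outer, scalp = (make_icosphere(subdivisions, r) for r in radii)
    return HeadModel(
        cortex=cortex, inner_skull=inner, outer_skull=outer, scalp=scalp,
        conductivities=conductivities,
    )


#: standard 10-20 positions as (label, theta, phi) where theta is the polar
#: angle from +z (vertex) and phi the azimuth from +x (right ear), degrees.
_1020_ANGLES = [
    ("Fp1", 72, 108), ("Fp2", 72, 72),
    ("F7", 72, 144), ("F3", 48, 129), ("Fz", 36, 90), ("F4", 48, 51), ("F8", 72, 36),
    ("T3", 72, 180), ("C3", 36, 180), ("Cz", 0, 0), ("C4", 36, 0), ("T4", 72, 0),
    ("T5", 72, 216), ("P3", 48, 231), ("Pz", 36, 270), ("P4", 48, 309), ("T6", 72, 324),
    ("O1", 72, 252), ("O2", 72, 288),
]


def make_1020_layout(scalp: TriMesh) -> SensorArray:
    """The 19-electrode 10-20 layout projected to a (spherical) scalp."""
    from .forward import project_sensors_to_scalp

    R = float(np.linalg.norm(scalp.vertices, axis=1).mean())
    pos = []
    for _, th, ph in _1020_ANGLES:
        th_r, ph_r = np.deg2rad(th), np.deg2rad(ph)
        pos.append(
            [
                R * np.sin(th_r) * np.cos(ph_r),
                R * np.sin(th_r) * np.sin(ph_r),
                R * np.cos(th_r),
            ]
        )
    arr = SensorArray(labels=[a[0] for a in _1020_ANGLES], positions=np.asarray(pos), kind="eeg")
    return project_sensors_to_scalp(arr, scalp)


# ---------------------------------------------------------------------------
# oscillatory source networks


@dataclass
class OscillatoryNetworkSpec:
    """Ground truth for a band-limited coupled oscillatory source network.

    ``coupling`` is a Hermitian coherency-target matrix with unit diagonal
    over the active set; the cross-spectral density of the active sources at
    in-band frequencies is ``amplitude**2 * profile(f) * coupling`` plus an
    independent ``noise_floor**2`` on every source.
    """

    n_sources: int
    active: tuple = (0, 1, 2)
    center_hz: float = 10.0
    bandwidth_hz: float = 2.0
    amplitude: float = 1.0
    coupling: np.ndarray | None = None  # (len(active), len(active)) Hermitian
    noise_floor: float = 0.05
    n_time: int = 6000
    sampling_rate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.active = tuple(int(i) for i in self.active)
        if any(i < 0 or i >= self.n_sources for i in self.active):
            raise ValueError("active indices out of range")
        if self.coupling is None:
            self.coupling = np.eye(len(self.active), dtype=complex)
        self.coupling = np.asarray(self.coupling, dtype=complex)
        k = len(self.active)
        if self.coupling.shape != (k, k):
            raise ValueError("coupling shape mismatch")
        if np.linalg.norm(self.coupling - self.coupling.conj().T) > 1e-10:
            raise ValueError("coupling must be Hermitian")
        if np.any(np.abs(np.diag(self.coupling) - 1.0) > 1e-10):
            raise ValueError("coupling diagonal must be 1")
        offs = self.coupling - np.diag(np.diag(self.coupling))
        if np.max(np.abs(np.linalg.eigvalsh(offs))) >= 1.0:
            raise ValueError("coupling spectral radius must be < 1 off the diagonal")


def _band_profile(freqs: np.ndarray, center: float, bandwidth: float) -> np.ndarray:
    """Gaussian band profile, peak 1 at the center frequency."""
    s = bandwidth / 2.0
    return np.exp(-0.5 * ((freqs - center) / s) ** 2)


def theoretical_cross_spectrum(spec: OscillatoryNetworkSpec, freqs: np.ndarray) -> np.ndarray:
    """Exact cross-spectral tensor (S x S x F) of the simulated sources on the
    one-sided FFT-coefficient scale used by ``spectral.cross_spectrum``.

    ``noise_floor**2`` is the flat one-sided spectral level of the per-source
    independent background, and ``amplitude**2`` the in-band peak level of the
    coupled component.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    S = spec.n_sources
    out = np.zeros((S, S, len(freqs)), dtype=complex)
    prof = _band_profile(freqs, spec.center_hz, spec.bandwidth_hz)
    act = np.asarray(spec.active)
    for fi in range(len(freqs)):
        M = np.zeros((S, S), dtype=complex)
        M[np.ix_(act, act)] = spec.amplitude**2 * prof[fi] * spec.coupling
        M[np.diag_indices(S)] += spec.noise_floor**2
        out[:, :, fi] = M
    return out


def simulate_oscillatory_sources(spec: OscillatoryNetworkSpec):
    """Simulate stationary Gaussian source series with an exactly known
    cross-spectrum, by complex-Gaussian spectral synthesis.

    Returns ``(TimeSeriesData, theoretical_tensor_fn)`` where the second item
    is a callable mapping a frequency grid to the exact cross-spectral tensor.
    """
    rng = np.random.default_rng(spec.seed)
    S, T = spec.n_sources, spec.n_time
    freqs = np.fft.rfftfreq(T, 1.0 / spec.sampling_rate)
    nb = len(freqs)
    prof = _band_profile(freqs, spec.center_hz, spec.bandwidth_hz)
    act = np.asarray(spec.active)
    k = len(act)
    # Cholesky of the active-set coherency
    Lc = np.linalg.cholesky(
        spec.coupling + 1e-12 * np.eye(k)
    )
    Z = np.zeros((S, nb), dtype=complex)
    # active sources: band-shaped coupled spectra
    w = (rng.standard_normal((k, nb)) + 1j * rng.standard_normal((k, nb))) / np.sqrt(2.0)
    Z[act] = spec.amplitude * np.sqrt(prof)[None, :] * (Lc @ w)
    # independent noise floor on every source
    wn = (rng.standard_normal((S, nb)) + 1j * rng.standard_normal((S, nb))) / np.sqrt(2.0)
    Z += spec.noise_floor * wn
    if spec.amplitude == 0 and spec.noise_floor == 0:
        Z[:] = 0.0
    # real series via inverse rfft; scale so the FFT-coefficient estimator
    # (see spectral.fft_coefficients) has expectation equal to the target
    Z[:, 0] = Z[:, 0].real
    if T % 2 == 0:
        Z[:, -1] = Z[:, -1].real
    x = np.fft.irfft(Z * np.sqrt(T / 2.0), n=T, axis=1)
    data = TimeSeriesData(
        data=x, sampling_rate=spec.sampling_rate,
        labels=[f"src{i}" for i in range(S)],
    )
    return data, lambda f: theoretical_cross_spectrum(spec, f)


def project_to_sensors(
    L: LeadField, sources: TimeSeriesData, snr_db: float | None = 10.0, seed: int = 0
) -> TimeSeriesData:
    """Forward-project source series to sensors, v = L j + white noise.

    ``snr_db = None`` gives the noiseless projection; otherwise white Gaussian
    noise is scaled so signal power / noise power matches the requested SNR.
    """
    if L.mode != "constrained":
        raise ValueError("projection requires an orientation-constrained lead field")
    if L.n_sources != sources.data.shape[0]:
        raise ValueError("lead field / source count mismatch")
    clean = L.matrix @ sources.data
    if snr_db is None:
        noisy = clean
    else:
        rng = np.random.default_rng(seed)
        p_sig = np.mean(clean**2)
        p_noise = p_sig / 10.0 ** (snr_db / 10.0)
        noisy = clean + rng.standard_normal(clean.shape) * np.sqrt(p_noise)
    labels = list(L.sensor_labels) or [f"ch{i}" for i in range(clean.shape[0])]
    return TimeSeriesData(data=noisy, sampling_rate=sources.sampling_rate, labels=labels)


# ---------------------------------------------------------------------------
# paired spectra tensors (MEG/EEG comparison fixture)


def make_paired_spectra_tensors(
    n_sources: int,
    n_freqs: int,
    n_cases: int,
    a_f=1.5,
    b_f=0.8,
    noise_sd: float = 0.1,
    seed: int = 7,
):
    """Paired MEG/EEG source-spectra tensors from the generative scaling model
    MEG = exp(a_f) * EEG**b_f * exp(noise).

    EEG spectra are log-normal; both tensors are strictly positive and shaped
    (sources, frequencies, cases).
    """
    rng = np.random.default_rng(seed)
    a = np.broadcast_to(np.asarray(a_f, dtype=np.float64), (n_freqs,))
    b = np.broadcast_to(np.asarray(b_f, dtype=np.float64), (n_freqs,))
    log_eeg = rng.standard_normal((n_sources, n_freqs, n_cases))
    noise = noise_sd * rng.standard_normal((n_sources, n_freqs, n_cases))
    log_meg = a[None, :, None] + b[None, :, None] * log_eeg + noise
    return np.exp(log_meg), np.exp(log_eeg)


def make_source_cap(cortex_mesh: TriMesh, n_sources: int = 500):
    """Source space on the upper spherical cap of a cortex fixture.

    Decimates the cortex mesh and keeps the ``n_sources`` vertices with the
    largest z -- the region under a 10-20 electrode cap, mimicking a cerebral
    cortex that does not extend below the head's equator.  Returns
    ``(positions, normals, mesh, kept_indices)`` where ``mesh`` is the
    decimated mesh the indices refer to (for neighborhood lookups).
    """
    from .mesh import resample_mesh

    target = min(max(2 * n_sources + 26, 12), cortex_mesh.n_vertices)
    dec = resample_mesh(cortex_mesh, target)
    # decimation lets vertices drift off the sphere by up to a sagitta; put
    # the fixture sources back on the cortex radius so nesting margins hold
    R = float(np.linalg.norm(cortex_mesh.vertices, axis=1).mean())
    dec.vertices *= (R / np.linalg.norm(dec.vertices, axis=1))[:, None]
    order = np.argsort(dec.vertices[:, 2])[::-1][:n_sources]
    kept = np.sort(order)
    pos = dec.vertices[kept]
    normals = pos / np.linalg.norm(pos, axis=1)[:, None]
    return pos, normals, dec, kept


def proximity_unstable_leadfield_provider(
    radii=(0.082, 0.088, 0.092),
    sigmas=(0.33, 0.0042, 0.33),
    critical_distance_m: float = 0.002,
    seed: int = 0,
):
    """A tested-lead-field provider that emulates boundary-integration
    numerical instability near the inner skull.

    Returns ``provider(head, src, sensors) -> LeadField``: the three-shell
    analytic model whose column j is corrupted by deterministic pseudo-noise
    with magnitude growing as the source's distance to the inner-skull mesh
    falls below ``critical_distance_m`` -- the failure mode that makes
    surface-surface distance a lead-field quality factor.  The corruption is
    a pure function of (seed, source index), so recomputing after a geometry
    correction is reproducible.
    """
    from .forward import three_shell_sphere_leadfield_eeg, apply_orientation_constraint
    from .mesh import surface_surface_distances, vertex_normals

    def provider(head, src, sensors):
        lf = three_shell_sphere_leadfield_eeg(
            SourceSpaceView(src.positions), sensors, radii=radii, sigmas=sigmas
        )
        normals = src.orientations
        if normals is None:
            normals = src.positions / np.linalg.norm(src.positions, axis=1)[:, None]
        lf = apply_orientation_constraint(lf, normals)
        dist = surface_surface_distances(src.positions, head.inner_skull)
        M = lf.matrix.copy()
        for j in np.flatnonzero(dist < critical_distance_m):
            strength = critical_distance_m / max(dist[j], 1e-6) - 1.0
            rng_j = np.random.default_rng((seed, int(j)))
            M[:, j] += rng_j.standard_normal(M.shape[0]) * np.abs(M[:, j]).mean() * (
                1.0 + 3.0 * strength
            )
        return LeadField(
            M, mode="constrained", units=lf.units, reference="none",
            provenance="sphere", sensor_labels=list(lf.sensor_labels),
        )

    return provider


class SourceSpaceView:
    """Minimal positional source-space wrapper (free orientation)."""

    def __init__(self, positions):
        self.positions = np.asarray(positions, dtype=np.float64)
        self.orientations = None
        self.mode = "free"

    @property
    def n_sources(self):
        return len(self.positions)


# ---------------------------------------------------------------------------
# artifact injection


@dataclass
class ArtifactSpec:
    """A deterministic corruption: which kind, how strong, where."""

    kind: str  # {dent_inner_skull, jitter_sensors, noise_column, blur_mesh}
    magnitude: float
    targets: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.kind not in ("dent_inner_skull", "jitter_sensors", "noise_column", "blur_mesh"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def inject_artifact(obj, spec: ArtifactSpec):
    """Apply a deterministic artifact of the requested kind.

    * ``dent_inner_skull`` on a HeadModel: pull inner-skull vertices nearest
      to the target cortex vertices inward until they sit ``magnitude`` meters
      from those cortex points.
    * ``jitter_sensors`` on a SensorArray: displace every sensor by
      ``magnitude`` meters in a random direction.
    * ``noise_column`` on a LeadField: replace the target columns by
      independent Gaussian noise of matched scale.
    * ``blur_mesh`` on a TriMesh: ``magnitude``-weighted neighbor averaging.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "dent_inner_skull":
        head: HeadModel = obj
        inner = head.inner_skull.copy()
        cortex_pts = head.cortex.vertices[list(spec.targets)]
        from scipy.spatial import cKDTree

        tree = cKDTree(inner.vertices)
        for p in cortex_pts:
            _, vi = tree.query(p)
            d = inner.vertices[vi] - p
            nd = np.linalg.norm(d)
            if nd > spec.magnitude:
                inner.vertices[vi] = p + d / nd * spec.magnitude
        return HeadModel(
            cortex=head.cortex, inner_skull=inner, outer_skull=head.outer_skull,
            scalp=head.scalp, conductivities=head.conductivities,
            model_type=head.model_type, provenance=head.provenance,
        )
    if spec.kind == "jitter_sensors":
        # electrodes sit on the scalp, so misalignment slides them along the
        # surface: tangential displacement with the radial distance preserved
        sens: SensorArray = obj
        radial = sens.positions / np.linalg.norm(sens.positions, axis=1)[:, None]
        dirs = rng.standard_normal(sens.positions.shape)
        dirs -= np.einsum("ij,ij->i", dirs, radial)[:, None] * radial
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        moved = sens.positions + spec.magnitude * dirs
        moved *= (np.linalg.norm(sens.positions, axis=1) / np.linalg.norm(moved, axis=1))[:, None]
        return SensorArray(
            labels=list(sens.labels), positions=moved,
            kind=sens.kind, orientations=sens.orientations, reference=sens.reference,
        )
    if spec.kind == "noise_column":
        lf: LeadField = obj
        M = lf.matrix.copy()
        scale = np.std(M)
        for j in spec.targets:
            M[:, j] = rng.standard_normal(M.shape[0]) * scale * spec.magnitude
        return LeadField(
            M, mode=lf.mode, units=lf.units, reference="none",
            provenance=lf.provenance, sensor_labels=list(lf.sensor_labels),
        )
    if spec.kind == "blur_mesh":
        mesh: TriMesh = obj
        out = mesh.copy()
        e = mesh.edges()
        acc = np.zeros_like(out.vertices)
        cnt = np.zeros(out.n_vertices)
        for a, b in e:
            acc[a] += out.vertices[b]
            acc[b] += out.vertices[a]
            cnt[a] += 1
            cnt[b] += 1
        lam = min(spec.magnitude, 1.0)
        out.vertices = (1 - lam) * out.vertices + lam * acc / cnt[:, None]
        return out
    raise AssertionError
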