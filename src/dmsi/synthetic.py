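"""Synthetic MEG cohort generation.

Emulates the statistical structure of a clinical interictal-spike dataset so
the full analysis runs without any external data: a cortical surface with
dipoles normal to the surface, a 275-channel sensor array at 600 Hz, a
cohort of patients each with a ground-truth focal patch, and per-patient
"studies" — continuous recordings containing repeated spikes whose averaged
peak is source-localized.

Geometry
--------
The cortex stand-in is a "wavy sphere": Fibonacci-lattice points on the unit
sphere triangulated by their convex hull, then radially modulated by a smooth
angular function.  The modulation is essential — dipoles normal to a perfect
sphere are radial and magnetically silent in the spherical forward model —
and gives normals a realistic tangential component, with a depth/orientation
distribution that varies across the surface like gyral/sulcal cortex.

Signal model
------------
Each spike is a biphasic waveform (~70 ms) placed on the focus patch with
amplitudes tapering from the patch seed; sensor data are gain x sources plus
white sensor noise scaled to a target SNR, defined as the RMS of the
noiseless sensor signal within +/-25 ms of the peak over the noise RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .anatomy import CorticalMesh, FocusRegion, grow_patch
from .forward import GainMatrix, SensorArray, spherical_meg_gain

__all__ = [
    "CohortSpec",
    "Cohort",
    "PatientRecord",
    "StudyRecord",
    "wavy_cortex_mesh",
    "helmet_sensor_array",
    "spike_waveform",
    "simulate_study",
    "generate_cohort",
]


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Defaults reproduce the cohort scale of a typical clinical MEG series:
    28 patients contributing ~206 averaged-spike studies (truncated-geometric
    studies-per-patient distribution with mean ~7.4), 10 mm focal patches,
    20 spikes per study at SNR 5, 275 sensors, 600 Hz.
    """

    n_patients: int = 28
    mean_studies_per_patient: float = 7.357  # ~206 studies over 28 patients
    studies_per_patient: int | None = None  # fixed count overrides the distribution
    focus_radius_mm: float = 10.0
    spike_amplitude: float = 10.0  # dipole moment units (arbitrary, e.g. nAm)
    snr: float = 5.0
    n_epochs_per_study: int = 20
    sampling_rate_hz: float = 600.0
    n_sensors: int = 275
    mesh_vertices: int = 8000
    cortex_radius_mm: float = 70.0
    sensor_radius_mm: float = 120.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_sensors, self.mesh_vertices) <= 0:
            raise ValueError("counts must be positive")
        if self.n_epochs_per_study < 5:
            raise ValueError("studies need at least five spikes")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.focus_radius_mm <= 0:
            raise ValueError("focus radius must be positive")


@dataclass
class PatientRecord:
    patient_id: str
    focus: FocusRegion
    focus_seed: int


@dataclass
class StudyRecord:
    patient_id: str
    study_id: str
    recording: "object"  # SensorRecording


@dataclass
class Cohort:
    spec: CohortSpec
    mesh: CorticalMesh
    sensors: SensorArray
    gain: GainMatrix
    patients: list
    studies: list


def _fibonacci_directions(n: int, z_min: float = -1.0, z_max: float = 1.0) -> np.ndarray:
    """n unit vectors roughly equidistributed over the band z in [z_min, z_max]."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = z_max - (i + 0.5) * (z_max - z_min) / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = golden * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _radial_modulation(u: np.ndarray, waviness: float) -> np.ndarray:
    """Smooth angular modulation in [-waviness, waviness] (gyral folding stand-in)."""
    f = (
        np.sin(4.0 * u[:, 0] + 1.0) * np.sin(4.0 * u[:, 1])
        + np.cos(4.0 * u[:, 2])
        + 0.5 * np.sin(7.0 * u[:, 1] + 0.5)
    ) / 2.5
    return waviness * f


def wavy_cortex_mesh(
    n_vertices: int = 8000, radius_mm: float = 70.0, waviness: float = 0.12
) -> CorticalMesh:
    """Deterministic star-shaped cortical surface with ``n_vertices`` vertices.

    Fibonacci points on the unit sphere are triangulated by their convex
    hull (all points are extreme, so every vertex is kept), then pushed
    radially by a smooth modulation so the surface normals acquire
    tangential components.
    """
    u = _fibonacci_directions(n_vertices)
    hull = ConvexHull(u)
    r = radius_mm * (1.0 + _radial_modulation(u, waviness))
    vertices = u * r[:, None]
    return CorticalMesh.from_geometry(vertices, hull.simplices)


def helmet_sensor_array(
    n_sensors: int = 275, radius_mm: float = 120.0, z_min_frac: float = -0.35
) -> SensorArray:
    """Radial point magnetometers on a helmet-like spherical cap."""
    u = _fibonacci_directions(n_sensors, z_min=z_min_frac, z_max=1.0)
    return SensorArray(
        positions=u * radius_mm,
        orientations=u,
        names=[f"MEG{i + 1:03d}" for i in range(n_sensors)],
    )


def spike_waveform(
    t_s: np.ndarray, peak_s: float, width_s: float = 0.02, undershoot_s: float = 0.03
) -> np.ndarray:
    """Canonical biphasic spike: sharp positive lobe peaking at ``peak_s``
    followed by a slower negative undershoot (total duration ~70 ms)."""
    main = np.exp(-0.5 * ((t_s - peak_s) / (width_s / 2.355)) ** 2)
    under = -0.5 * np.exp(-0.5 * ((t_s - peak_s - undershoot_s) / (width_s / 1.5)) ** 2)
    # normalize so the value at the marker time is exactly 1
    peak_val = 1.0 - 0.5 * np.exp(-0.5 * (undershoot_s / (width_s / 1.5)) ** 2)
    return (main + under) / peak_val


def simulate_study(
    focus: FocusRegion,
    gain: GainMatrix,
    mesh: CorticalMesh,
    spec: CohortSpec,
    rng: np.random.Generator,
    focus_seed: int | None = None,
    spike_type: str = "spike1",
):
    """One continuous recording with ``n_epochs_per_study`` marked spikes.

    Source amplitudes taper from the patch seed as a Gaussian of scale half
    the patch radius; spikes are spaced ~2.5 s apart with +/-100 ms jitter.
    White sensor noise is scaled so that the RMS of the clean sensor signal
    within +/-25 ms of the spike peaks over the noise RMS equals
    ``spec.snr``.  An infinite SNR yields the clean signal exactly.
    """
    from .preprocess import SensorRecording

    if spec.snr <= 0:
        raise ValueError("snr must be positive")
    fs = spec.sampling_rate_hz
    n_spk = spec.n_epochs_per_study
    spacing = 2.5
    duration = n_spk * spacing + 2.0 * 1.5
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs

    peaks = 1.5 + spacing * np.arange(n_spk) + rng.uniform(-0.1, 0.1, size=n_spk)

    ids = focus.vertex_ids
    if focus_seed is None:
        center = mesh.vertices[ids].mean(axis=0)
    else:
        center = mesh.vertices[focus_seed]
    d = np.linalg.norm(mesh.vertices[ids] - center, axis=1)
    taper = np.exp(-(d**2) / (2.0 * (spec.focus_radius_mm / 2.0) ** 2))

    wave = np.zeros(n_t)
    for pk in peaks:
        sel = np.abs(t - pk) < 0.2  # spike support
        wave[sel] += spike_waveform(t[sel], pk)
    src = spec.spike_amplitude * taper[:, None] * wave[None, :]
    clean = gain.values[:, ids] @ src

    # clean-signal RMS restricted to +/-25 ms around the peaks
    mask = np.zeros(n_t, dtype=bool)
    for pk in peaks:
        mask |= np.abs(t - pk) <= 0.025
    rms = np.sqrt(np.mean(clean[:, mask] ** 2))
    noise_sd = 0.0 if np.isinf(spec.snr) else rms / spec.snr
    data = clean + noise_sd * rng.standard_normal(clean.shape)

    markers = [(float(pk), spike_type) for pk in peaks]
    return SensorRecording(data, fs, list(gain.channel_names), markers)


def generate_cohort(spec: CohortSpec, simulate_recordings: bool = True) -> Cohort:
    """Full synthetic cohort: mesh, gain, per-patient focus, per-study recording.

    ``simulate_recordings=False`` produces the cohort manifest (patients,
    foci, study records with ``recording=None``) without synthesizing sensor
    data; the same seed stream is consumed either way, so the cohort
    structure is identical.

    Deterministic given ``spec.master_seed``: per-patient and per-study child
    seeds are derived through ``np.random.SeedSequence.spawn``.  Focus seeds
    are drawn among vertices whose gain-column norm exceeds the cohort
    median, which excludes near-radial (magnetically quasi-silent) and
    poorly covered deep sources, mirroring the cortical placement of
    clinically delineated foci.
    """
    mesh = wavy_cortex_mesh(spec.mesh_vertices, spec.cortex_radius_mm)
    sensors = helmet_sensor_array(spec.n_sensors, spec.sensor_radius_mm)
    gain = spherical_meg_gain(mesh, sensors)

    col_norms = np.linalg.norm(gain.values, axis=0)
    eligible = np.flatnonzero(col_norms > np.median(col_norms))

    max_extent = np.linalg.norm(
        mesh.vertices - mesh.vertices.mean(axis=0), axis=1
    ).max()
    if spec.focus_radius_mm > 2.0 * max_extent:
        raise ValueError("focus radius exceeds the mesh extent")

    ss = np.random.SeedSequence(spec.master_seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    patients: list[PatientRecord] = []
    studies: list[StudyRecord] = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:02d}"
        seed_vertex = int(cohort_rng.choice(eligible))
        focus = grow_patch(mesh, seed_vertex, spec.focus_radius_mm, label=pid)
        patients.append(PatientRecord(pid, focus, seed_vertex))

        if spec.studies_per_patient is not None:
            n_st = spec.studies_per_patient
        else:
            # geometric on {1, 2, ...}; mean ~ spec.mean_studies_per_patient
            p_geom = 1.0 / spec.mean_studies_per_patient
            n_st = int(min(cohort_rng.geometric(p_geom), 25))
        child_seeds = ss.spawn(n_st)
        for j in range(n_st):
            rec = None
            if simulate_recordings:
                rng = np.random.default_rng(child_seeds[j])
                rec = simulate_study(
                    focus, gain, mesh, spec, rng, focus_seed=seed_vertex
                )
            studies.append(StudyRecord(pid, f"{pid}_S{j + 1:02d}", rec))
    return Cohort(spec, mesh, sensors, gain, patients, studies)
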