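"""Forward modeling: the sensors x sources gain matrix.

The gain (lead field) matrix G maps dipole amplitudes on the cortical mesh to
MEG sensor measurements.  Here it is built analytically for a current dipole
in a homogeneous conducting sphere (the closed-form magnetic field solution),
with sensors modeled as point magnetometers.  Two well-known properties of
this model are exploited by the test-suite: dipoles oriented radially are
magnetically silent, and the conductivity value does not enter the external
field at all (it is carried as metadata only).

Realistic head models (BEM/FEM) are out of scope; externally computed gain
matrices can be imported from HDF5 or dense text instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import CorticalMesh

__all__ = ["SensorArray", "GainMatrix", "spherical_meg_gain", "save_gain", "load_gain"]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class SensorArray:
    """MEG sensor geometry: positions (mm), unit orientations, unique names."""

    positions: np.ndarray
    orientations: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != self.orientations.shape or self.positions.shape[1] != 3:
            raise ValueError("positions/orientations must be matching (n, 3) arrays")
        if not np.allclose(np.linalg.norm(self.orientations, axis=1), 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit vectors")
        if len(self.names) != len(self.positions):
            raise ValueError("one name per sensor required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sensor names must be unique")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GainMatrix:
    """Channels x sources forward operator.

    Values are in T per unit dipole moment on an arbitrary consistent scale;
    every solver downstream is invariant to a global rescaling of the gain
    combined with a matching rescaling of the data.
    """

    values: np.ndarray
    channel_names: list[str]
    conductivity_s_per_m: float = 0.33  # metadata only; no effect on MEG field

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("gain values must be 2-D (channels x sources)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gain matrix contains non-finite entries")
        if len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names must match gain rows")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def source_count(self) -> int:
        return self.values.shape[1]


def spherical_meg_gain(
    mesh: CorticalMesh,
    sensors: SensorArray,
    sphere_center: np.ndarray | None = None,
) -> GainMatrix:
    """Gain matrix for current dipoles in a homogeneous conducting sphere.

    Implements the closed-form external magnetic field of a current dipole Q
    at ``r0`` inside a conducting sphere, evaluated at sensor position ``r``
    (both relative to the sphere center)::

        B(r) = mu0 / (4 pi F^2) * (F Q x r0 - (Q x r0 . r) grad F)
        F    = a (r a + r^2 - r0 . r),   a = |r - r0|

    Dipole moments are the mesh vertex normals (unit moment per source);
    the measurement is the projection of B onto the sensor orientation.
    A dipole at the center, or oriented radially, produces zero field.

    Raises
    ------
    ValueError
        If any source lies outside the innermost sensor radius.
    """
    if sphere_center is None:
        sphere_center = mesh.vertices.mean(axis=0)
    sphere_center = np.asarray(sphere_center, dtype=float)

    r0 = mesh.vertices - sphere_center  # (p, 3)
    sens = sensors.positions - sphere_center  # (c, 3)
    src_rad = np.linalg.norm(r0, axis=1)
    sens_rad = np.linalg.norm(sens, axis=1)
    if src_rad.max() >= sens_rad.min():
        raise ValueError(
            f"sources must lie strictly inside the sensor shell "
            f"(max source radius {src_rad.max():.1f} mm >= min sensor radius "
            f"{sens_rad.min():.1f} mm)"
        )

    q_x_r0 = np.cross(mesh.normals, r0)  # (p, 3)
    G = np.empty((len(sens), mesh.n_vertices))
    for s in range(len(sens)):
        r = sens[s]
        rn = sens_rad[s]
        a_vec = r[None, :] - r0
        a = np.linalg.norm(a_vec, axis=1)
        ar = a_vec @ r
        F = a * (rn * a + rn**2 - r0 @ r)
        c1 = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
        c2 = a + 2.0 * rn + ar / a
        gradF = c1[:, None] * r[None, :] - c2[:, None] * r0
        B = (MU0_OVER_4PI / F[:, None] ** 2) * (
            F[:, None] * q_x_r0 - (q_x_r0 @ r)[:, None] * gradF
        )
        G[s] = B @ sensors.orientations[s]
    return GainMatrix(G, list(sensors.names))


def save_gain(gain: GainMatrix, path) -> None:
    """Write a gain matrix to HDF5 (``.h5``/``.hdf5``) or dense text."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("values", data=gain.values)
            d.attrs["units"] = "T per unit dipole moment"
            f.create_dataset(
                "channel_names",
                data=np.array(gain.channel_names, dtype=h5py.string_dtype()),
            )
            f.attrs["conductivity_s_per_m"] = gain.conductivity_s_per_m
    else:
        header = " ".join(gain.channel_names)
        np.savetxt(path, gain.values, fmt="%.17g", header=header)


def load_gain(path, expected_sources: int | None = None, strict: bool = True) -> GainMatrix:
    """Read and validate a gain matrix written by :func:`save_gain`.

    ``expected_sources`` (typically the mesh vertex count) enforces the
    column dimension; ``strict`` additionally rejects all-zero sensor rows.
    NaN entries are always rejected.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()]]
            cond = float(f.attrs.get("conductivity_s_per_m", 0.33))
    else:
        values = np.loadtxt(path, ndmin=2)
        with open(path) as fh:
            first = fh.readline()
        names = first.lstrip("# ").split()
        cond = 0.33
    if not np.all(np.isfinite(values)):
        raise ValueError("gain file contains NaN or infinite entries")
    if expected_sources is not None and values.shape[1] != expected_sources:
        raise ValueError(
            f"gain has {values.shape[1]} sources, mesh has {expected_sources} vertices"
        )
    if strict and np.any(np.all(values == 0.0, axis=1)):
        raise ValueError("gain contains an all-zero sensor row")
    if len(names) != values.shape[0]:
        names = [f"CH{i:03d}" for i in range(values.shape[0])]
    return GainMatrix(values, names, conductivity_s_per_m=cond)
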