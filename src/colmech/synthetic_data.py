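"""Synthetic inputs for the pipeline: pulling trajectories, MSAs, EPR
sweeps and FOX absorbance plates.

The pulling simulator is an overdamped (inertia-free) Langevin bead-spring
model.  Its observable of interest — the time-averaged scalar bond force —
is integrator-independent at steady state, which is why no velocity-Verlet
machinery is carried around.  External constant forces of
``per_chain_force * weight`` are applied axially to the chain end beads
that sit at the axial boundaries of the segment (+z at the top end, -z at
the bottom end); chain termini inside the segment (telopeptides) are left
unloaded, so the load must cross the segment through backbone and
crosslinks.

Everything here is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .constants import BOLTZMANN_NN_NM
from .fibril_topology import (
    CROSSLINK,
    FibrilTopology,
    generate_coordinates,
    planted_redox_positions,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# bead-spring pulling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the overdamped Langevin pulling run.

    Units: nm, nN, K; time is measured in units of the friction time
    ``tau = friction * nm / nN`` (friction is the drag coefficient per
    bead).  ``rest_length=None`` takes per-bond rest lengths from the
    initial coordinates, so the system starts force-free.
    """

    spring_constant: float = 10.0          # nN/nm, backbone
    crosslink_spring_constant: float | None = None  # defaults to backbone value
    rest_length: float | None = None       # nm; None -> from initial coords
    temperature: float = 300.0             # K
    friction: float = 1.0                  # nN tau / nm per bead
    timestep: float = 0.005                # tau
    n_steps: int = 40_000
    record_every: int = 100
    seed: int = 0
    per_chain_force: float = 1.0           # nN
    loading_mode: str = "equal"            # "equal" | "shear"
    shear_weights: tuple[float, ...] | None = None  # per helix
    equilibration_fraction: float = 0.1
    rupture_check_factor: float = 5.0      # flag bonds beyond factor*rest
    boundary_tol: float | None = None      # nm; None -> axial_rise / 2

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.n_steps < 1 or self.record_every < 1:
            raise ValidationError("n_steps and record_every must be >= 1")
        if self.loading_mode not in ("equal", "shear"):
            raise ValidationError(f"unknown loading_mode {self.loading_mode!r}")
        if self.shear_weights is not None:
            w = np.asarray(self.shear_weights, dtype=float)
            if np.any(w < 0):
                raise ValidationError("shear weights must be >= 0")
            if self.loading_mode == "equal" and not np.allclose(w, 1.0):
                raise ValidationError("equal loading requires all weights = 1")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValidationError("equilibration_fraction must be in [0, 1)")

    @property
    def kT(self) -> float:
        """Thermal energy in nN nm."""
        return BOLTZMANN_NN_NM * self.temperature


@dataclass
class Trajectory:
    """Recorded frames of a pulling run plus everything needed to re-derive
    bond forces (per-bond spring constants and rest lengths)."""

    topology: FibrilTopology
    frames: np.ndarray                  # (n_frames, n_sites, 3), nm
    params: SimulationParams
    bond_rest_lengths: np.ndarray       # aligned with topology.bonds
    bond_spring_constants: np.ndarray
    equilibration_frames: int
    rupture_flag: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def retained_frames(self) -> np.ndarray:
        """Frames after the equilibration prefix (the ones analyses use)."""
        return self.frames[self.equilibration_frames:]


def _external_forces(
    topology: FibrilTopology, params: SimulationParams
) -> np.ndarray:
    """Per-bead constant external force vector (n_sites, 3)."""
    sites = topology.sites
    z = sites.axial_coord.values
    zmin, zmax = z.min(), z.max()
    tol = (
        params.boundary_tol
        if params.boundary_tol is not None
        else topology.config.axial_rise / 2.0
    )
    if params.shear_weights is not None:
        w = np.asarray(params.shear_weights, dtype=float)
        if len(w) != topology.config.n_helices:
            raise ValidationError(
                "shear_weights must provide one weight per helix"
            )
        if params.loading_mode == "shear" and not np.isclose(
            w.sum(), topology.config.n_helices
        ):
            raise ValidationError(
                "shear weights must sum to n_helices (load conservation)"
            )
    else:
        w = np.ones(topology.config.n_helices)

    fext = np.zeros((topology.n_sites, 3))
    group = sites.groupby(["helix_id", "chain_id"], sort=False)
    for (helix, _chain), idx in group.indices.items():
        idx = np.asarray(idx)
        f = params.per_chain_force * w[int(helix)]
        top = idx[np.argmax(z[idx])]
        bottom = idx[np.argmin(z[idx])]
        if z[top] >= zmax - tol:
            fext[top, 2] += f
        if z[bottom] <= zmin + tol:
            fext[bottom, 2] -= f
    return fext


def simulate_pulling(
    topology: FibrilTopology,
    params: SimulationParams | None = None,
    coords: np.ndarray | None = None,
) -> Trajectory:
    """Integrate overdamped Langevin dynamics of the bead-spring fibril.

    ``x <- x + dt/gamma * (F_springs + F_ext) + sqrt(2 kT dt/gamma) * xi``.
    The first ``equilibration_fraction`` of recorded frames is marked as
    equilibration and excluded from downstream averaging by default.
    Raises a runtime error on diverging coordinates (too large a timestep);
    sets ``rupture_flag`` if any bond exceeds the rupture-check length.
    """
    params = params or SimulationParams()
    if len(topology.bonds) == 0:
        raise StructuralError("topology has no bonds to integrate")
    if coords is None:
        coords = generate_coordinates(topology, seed=params.seed)
    x = np.array(coords, dtype=float)
    if x.shape != (topology.n_sites, 3):
        raise StructuralError("coordinate array does not match site count")

    bi = topology.bonds.i
    bj = topology.bonds.j
    is_xl = topology.bonds.kind == CROSSLINK
    k_xl = (
        params.crosslink_spring_constant
        if params.crosslink_spring_constant is not None
        else params.spring_constant
    )
    kbond = np.where(is_xl, k_xl, params.spring_constant).astype(float)
    if params.rest_length is None:
        d0 = x[bi] - x[bj]
        r0 = np.linalg.norm(d0, axis=1)
    else:
        r0 = np.full(len(bi), float(params.rest_length))

    fext = _external_forces(topology, params)
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    mobility = dt / params.friction
    noise_scale = np.sqrt(2.0 * params.kT * dt / params.friction)

    n = topology.n_sites
    n_frames = params.n_steps // params.record_every
    frames = np.empty((n_frames, n, 3), dtype=float)
    rupture = False
    frame = 0
    for step in range(params.n_steps):
        d = x[bi] - x[bj]
        length = np.sqrt(np.einsum("ij,ij->i", d, d))
        coeff = -kbond * (length - r0) / np.maximum(length, 1e-12)
        fb = coeff[:, None] * d
        fs = np.empty_like(x)
        for comp in range(3):
            fs[:, comp] = np.bincount(bi, weights=fb[:, comp], minlength=n)
            fs[:, comp] -= np.bincount(bj, weights=fb[:, comp], minlength=n)
        x = x + mobility * (fs + fext) + noise_scale * rng.standard_normal((n, 3))
        if (step + 1) % params.record_every == 0:
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
                raise RuntimeError(
                    "integration diverged; use a smaller timestep "
                    "(need timestep << friction / spring_constant)"
                )
            if np.any(length > params.rupture_check_factor * np.maximum(r0, 1e-3)):
                rupture = True
            frames[frame] = x
            frame += 1

    return Trajectory(
        topology=topology,
        frames=frames,
        params=params,
        bond_rest_lengths=r0,
        bond_spring_constants=kbond,
        equilibration_frames=int(round(params.equilibration_fraction * n_frames)),
        rupture_flag=rupture,
        metadata={"seed": params.seed, "record_every": params.record_every},
    )


# ---------------------------------------------------------------------------
# trajectory text I/O (multi-frame XYZ + sidecar)
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, out_prefix: str | Path) -> dict[str, Path]:
    """Write frames as multi-frame XYZ text plus a JSON metadata sidecar and
    a TSV bond table (rest lengths and spring constants)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    xyz = out_prefix.with_suffix(".xyz")
    names = traj.topology.sites.residue.values
    with open(xyz, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.frames.shape[1]}\nframe {f}\n")
            for name, (px, py, pz) in zip(names, traj.frames[f]):
                fh.write(f"{name} {px:.6f} {py:.6f} {pz:.6f}\n")
    meta = out_prefix.parent / (out_prefix.name + ".meta.json")
    with open(meta, "w") as fh:
        json.dump(
            {
                "n_frames": int(traj.n_frames),
                "equilibration_frames": int(traj.equilibration_frames),
                "rupture_flag": bool(traj.rupture_flag),
                "params": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(traj.params).items()
                },
            },
            fh,
            indent=1,
        )
    bonds = out_prefix.parent / (out_prefix.name + ".trajbonds.tsv")
    pd.DataFrame(
        {
            "i": traj.topology.bonds.i,
            "j": traj.topology.bonds.j,
            "kind": traj.topology.bonds.kind,
            "rest_length": traj.bond_rest_lengths,
            "spring_constant": traj.bond_spring_constants,
        }
    ).to_csv(bonds, sep="\t", index=False)
    return {"xyz": xyz, "meta": meta, "bonds": bonds}


def read_trajectory(out_prefix: str | Path, topology: FibrilTopology) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    out_prefix = Path(out_prefix)
    with open(out_prefix.parent / (out_prefix.name + ".meta.json")) as fh:
        meta = json.load(fh)
    pdict = meta["params"]
    if pdict.get("shear_weights") is not None:
        pdict["shear_weights"] = tuple(pdict["shear_weights"])
    params = SimulationParams(**pdict)
    bonds = pd.read_csv(
        out_prefix.parent / (out_prefix.name + ".trajbonds.tsv"), sep="\t"
    )
    frames = []
    with open(out_prefix.with_suffix(".xyz")) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            n = int(header)
            fh.readline()
            block = np.array(
                [fh.readline().split()[1:4] for _ in range(n)], dtype=float
            )
            frames.append(block)
    frames = np.array(frames)
    if frames.shape[0] != meta["n_frames"]:
        raise StructuralError("frame count mismatch between XYZ and sidecar")
    return Trajectory(
        topology=topology,
        frames=frames,
        params=params,
        bond_rest_lengths=bonds.rest_length.values,
        bond_spring_constants=bonds.spring_constant.values,
        equilibration_frames=int(meta["equilibration_frames"]),
        rupture_flag=bool(meta["rupture_flag"]),
    )


# ---------------------------------------------------------------------------
# synthetic multiple sequence alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticMsaSpec:
    """Recipe for a vertebrate-like MSA with planted residue enrichment.

    At each planted position the class residue appears with
    ``enrichment_probability``; elsewhere the reference residue is kept
    with probability ``1 - background_rate`` and substituted uniformly
    otherwise.  The generator emits gapless alignments of reference length.
    """

    reference: str
    n_sequences: int = 64
    reference_id: str = "reference"
    planted: Mapping[str, Sequence[int]] = field(default_factory=dict)  # 1-based
    enrichment_probability: float = 0.9
    background_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for p in (self.enrichment_probability, self.background_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for cls, positions in self.planted.items():
            for pos in positions:
                if not 1 <= pos <= len(self.reference):
                    raise ValidationError(
                        f"planted position {pos} for class {cls!r} is outside "
                        f"the reference (length {len(self.reference)})"
                    )


def default_msa_spec(topology: FibrilTopology, family: str = "A1",
                     **overrides) -> SyntheticMsaSpec:
    """MSA spec whose planted Tyr/Phe/Met positions match the synthetic
    chain sequences' aromatic clusters around crosslink acceptors."""
    return SyntheticMsaSpec(
        reference=topology.sequences[family],
        planted=planted_redox_positions(topology.config),
        **overrides,
    )


def generate_msa(spec: SyntheticMsaSpec):
    """Generate the alignment as a ``Bio.Align.MultipleSeqAlignment``.

    The reference is included as the first record (and is itself subject to
    planting, so ``enrichment_probability=1`` plants the class residue in
    every sequence).
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(spec.seed)
    L = len(spec.reference)
    planted_at: dict[int, str] = {}
    for cls, positions in spec.planted.items():
        for pos in positions:
            planted_at[pos - 1] = cls

    records = []
    for i in range(spec.n_sequences):
        if i == 0:
            seq = list(spec.reference)
            for col, cls in planted_at.items():
                seq[col] = cls
            rid = spec.reference_id
        else:
            subs = rng.random(L) < spec.background_rate
            draws = rng.integers(len(AMINO_ACIDS), size=L)
            seq = [
                AMINO_ACIDS[draws[c]] if subs[c] else spec.reference[c]
                for c in range(L)
            ]
            for col, cls in planted_at.items():
                if rng.random() < spec.enrichment_probability:
                    seq[col] = cls
            rid = f"seq{i:04d}"
        records.append(SeqRecord(Seq("".join(seq)), id=rid, description=""))
    return MultipleSeqAlignment(records)


def write_msa_fasta(alignment, path: str | Path) -> Path:
    from Bio import AlignIO

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        AlignIO.write(alignment, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# noisy EPR sweeps
# ---------------------------------------------------------------------------

def generate_epr_sweep(
    gtensor, params=None, noise_sd: float = 0.0, seed: int = 0, **acq_kwargs
):
    """Powder spectrum plus seeded Gaussian noise of standard deviation
    ``noise_sd`` (in units of the unit-normalized clean intensity)."""
    from . import epr_spectra

    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if params is None:
        params = epr_spectra.AcquisitionParams(**acq_kwargs)
    clean = epr_spectra.powder_spectrum(gtensor, params)
    rng = np.random.default_rng(seed)
    noisy = clean.intensity + rng.normal(0.0, noise_sd, size=clean.intensity.shape)
    return epr_spectra.Spectrum(
        field_mT=clean.field_mT, intensity=noisy, params=params
    )


# ---------------------------------------------------------------------------
# synthetic FOX absorbance plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoxCalibration:
    """Linear 595 nm absorbance calibration: A = intercept + slope * [H2O2].

    Defaults emulate a kit-style xylenol orange working reagent read on a
    plate reader: 0.02 absorbance units per µM on top of a 0.05 blank.
    """

    slope: float = 0.02      # absorbance per µM
    intercept: float = 0.05  # absorbance

    def __post_init__(self):
        if self.slope == 0:
            raise ValidationError("calibration slope must be nonzero")


def generate_fox_plate(
    true_delta_uM: float = 1.0,
    calibration: FoxCalibration | None = None,
    replicates: int = 3,
    noise_sd: float = 0.001,
    seed: int = 0,
    times_min: Sequence[float] = (0.0, 30.0, 60.0),
    baseline_uM: float = 2.0,
) -> pd.DataFrame:
    """Paired pulled/untreated 595 nm absorbance wells.

    The pulled condition carries a hydrogen peroxide concentration
    ``baseline + true_delta_uM``; the untreated condition sits at the
    baseline.  ``noise_sd`` is absorbance noise per well (plate-reader and
    pipetting repeatability).  Columns: condition, time_min, well,
    absorbance.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    calibration = calibration or FoxCalibration()
    rng = np.random.default_rng(seed)
    rows = []
    for t in times_min:
        for condition, conc in (
            ("untreated", baseline_uM),
            ("pulled", baseline_uM + true_delta_uM),
        ):
            for well in range(replicates):
                a = calibration.intercept + calibration.slope * conc
                a += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "condition": condition,
                        "time_min": float(t),
                        "well": well,
                        "absorbance": a,
                    }
                )
    return pd.DataFrame(rows)
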