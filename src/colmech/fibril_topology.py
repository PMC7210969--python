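"""Coarse-grained, D-periodic, crosslinked collagen-I fibril segments.

The model is one bead per residue.  A fibril segment spans exactly one
D-period (67 nm by default): the axial window ``[0, D]``.  Each of the
``n_helices`` triple helices is a molecule column with a stagger class
``t = helix_id % 5``; molecule residues are laid on the axis at
``z = (seq_index - 1 - t * stagger + z_offset) * axial_rise`` and residues
falling outside the window are truncated.  Because the molecule is shorter
than five stagger periods, the five classes all coexist only in the overlap
region; the gap region holds four — the classic Hodge–Petruska picture.

Divalent HLKNL crosslinks connect a telopeptide lysine donor of one helix to
a helical hydroxylysine acceptor of an adjacent helix, one N-terminal and
one C-terminal link per adjacency pair.  Hydroxylysine and hydroxyproline
are written as lowercase ``k`` / ``p`` in sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError, ValidationError

BACKBONE = "backbone"
CROSSLINK = "crosslink"

#: residue codes accepted at crosslink positions: lysine or hydroxylysine
_LYSINE_LIKE = {"K", "k"}


@dataclass(frozen=True)
class CrosslinkRules:
    """Sequence positions (1-based) taking part in HLKNL crosslinks.

    ``donor_n`` must lie in the N-telopeptide and ``donor_c`` in the
    C-telopeptide; acceptors are helical hydroxylysines.  ``donor_chain`` /
    ``acceptor_chain`` select which of the three chains of a helix carries
    the link (default: the first α1 chain).  ``axial_cutoff`` is the largest
    admissible axial donor–acceptor separation in nm.
    """

    donor_n: int = 9
    acceptor_n: int = 940
    donor_c: int = 1031
    acceptor_c: int = 90
    donor_chain: int = 0
    acceptor_chain: int = 0
    axial_cutoff: float = 1.5


@dataclass(frozen=True)
class FibrilConfig:
    """Geometry and crosslinking parameters of a fibril segment.

    Defaults describe the standard segment: 37 triple helices, a 67 nm
    D-period with a 234-residue stagger (axial rise 67/234 ≈ 0.2863 nm per
    residue) and chains of 1039 residues, which yields an overlap fraction
    of 107/234 ≈ 0.457 of the period.
    """

    n_helices: int = 37
    D: float = 67.0
    stagger_residues: int = 234
    axial_rise: float | None = None
    chain_length: int = 1039
    z_offset_residues: int = 5
    overlap_fraction: float | None = None
    chain_composition: tuple[str, str, str] = ("A1", "A1", "A2")
    adjacency: tuple[tuple[int, int], ...] | None = None
    crosslink_rules: CrosslinkRules = field(default_factory=CrosslinkRules)
    lattice_spacing: float = 1.5
    telo_n: tuple[int, int] = (1, 16)
    telo_c: tuple[int, int] | None = None

    def __post_init__(self):
        if self.n_helices < 1:
            raise ConfigurationError("n_helices must be >= 1")
        if self.axial_rise is None:
            object.__setattr__(self, "axial_rise", self.D / self.stagger_residues)
        if abs(self.axial_rise * self.stagger_residues - self.D) > 1e-9:
            raise ConfigurationError(
                "axial_rise * stagger_residues must equal D within 1e-9 nm"
            )
        if self.overlap_fraction is None:
            # axial extent of the most-staggered class = overlap extent
            frac = (
                self.chain_length - 1 - 4 * self.stagger_residues + self.z_offset_residues
            ) / self.stagger_residues
            object.__setattr__(self, "overlap_fraction", frac)
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ConfigurationError(
                f"overlap_fraction must lie in (0, 1), got {self.overlap_fraction}"
            )
        if self.telo_c is None:
            object.__setattr__(
                self, "telo_c", (self.chain_length - 15, self.chain_length)
            )
        if self.adjacency is None:
            object.__setattr__(
                self, "adjacency", default_adjacency(self.n_helices)
            )
        for a, b in self.adjacency:
            if not (0 <= a < self.n_helices and 0 <= b < self.n_helices):
                raise ConfigurationError(
                    f"adjacency pair ({a}, {b}) references a missing helix "
                    f"(n_helices={self.n_helices})"
                )
            if a == b:
                raise ConfigurationError("adjacency pair joins a helix to itself")

    @property
    def n_stagger_classes(self) -> int:
        return 5

    def stagger_class(self, helix_id: int) -> int:
        return helix_id % self.n_stagger_classes

    def is_telopeptide(self, seq_index: int) -> bool:
        return (
            self.telo_n[0] <= seq_index <= self.telo_n[1]
            or self.telo_c[0] <= seq_index <= self.telo_c[1]
        )


def default_adjacency(n_helices: int, max_pairs: int = 6) -> tuple[tuple[int, int], ...]:
    """Fixture list of crosslink-eligible helix pairs.

    Pairs a class-0 helix ``5*i`` with the class-4 helix ``5*i + 4``, capped
    at ``max_pairs`` pairs so that the default 37-helix segment carries the
    canonical six crosslinked pairs (12 HLKNL crosslinks).  This list stands
    in for crystallographic lateral packing, which is outside the model.
    """
    pairs = []
    for i in range(max_pairs):
        a, b = 5 * i, 5 * i + 4
        if b >= n_helices:
            break
        pairs.append((a, b))
    return tuple(pairs)


def mini_config(n_helices: int = 10) -> FibrilConfig:
    """A reduced-geometry segment (stagger 50) for fast simulations.

    Same five-class structure and crosslink recipe as the default segment,
    ~1350 beads instead of ~23 000 at ``n_helices=10``.
    """
    S = 50
    return FibrilConfig(
        n_helices=n_helices,
        D=S * (67.0 / 234.0),
        stagger_residues=S,
        axial_rise=67.0 / 234.0,
        chain_length=221,
        z_offset_residues=2,
        telo_n=(1, 4),
        telo_c=(219, 221),
        crosslink_rules=CrosslinkRules(
            donor_n=3, acceptor_n=201, donor_c=219, acceptor_c=17
        ),
        adjacency=default_adjacency(n_helices, max_pairs=2),
    )


@dataclass(frozen=True)
class ResidueSite:
    helix_id: int
    chain_id: int
    seq_index: int
    residue: str
    axial_coord: float
    region: str
    family: str


@dataclass(frozen=True)
class Crosslink:
    id: int
    kind: str
    terminal: str  # "N" or "C"
    donor: int  # site index
    acceptor: int  # site index


@dataclass
class BondedTopology:
    """Harmonic bond table: site index pairs plus a bond-kind label."""

    i: np.ndarray
    j: np.ndarray
    kind: np.ndarray  # array of str, BACKBONE or CROSSLINK

    def __len__(self) -> int:
        return len(self.i)

    @classmethod
    def empty(cls) -> "BondedTopology":
        return cls(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object),
        )

    def append(self, i: int, j: int, kind: str) -> None:
        self.i = np.append(self.i, i)
        self.j = np.append(self.j, j)
        self.kind = np.append(self.kind, kind)


@dataclass
class FibrilTopology:
    """A built fibril segment: sites, crosslinks and bonds.

    ``sites`` is a DataFrame with columns ``helix_id, chain_id, seq_index,
    residue, axial_coord, region, family``; row order is the canonical site
    index used everywhere (bonds, crosslinks, coordinates, trajectories).
    """

    config: FibrilConfig
    sites: pd.DataFrame
    crosslinks: list[Crosslink]
    bonds: BondedTopology
    sequences: Mapping[str, str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, index: int) -> ResidueSite:
        row = self.sites.iloc[index]
        return ResidueSite(
            int(row.helix_id), int(row.chain_id), int(row.seq_index),
            str(row.residue), float(row.axial_coord), str(row.region),
            str(row.family),
        )

    def site_index(self, helix_id: int, chain_id: int, seq_index: int) -> int:
        key = (helix_id, chain_id, seq_index)
        try:
            return self._site_lookup[key]
        except AttributeError:
            lookup = {
                (int(h), int(c), int(s)): idx
                for idx, (h, c, s) in enumerate(
                    zip(self.sites.helix_id.values,
                        self.sites.chain_id.values,
                        self.sites.seq_index.values)
                )
            }
            object.__setattr__(self, "_site_lookup", lookup)
            return lookup[key]
        except KeyError:
            raise KeyError(f"no site for helix {helix_id} chain {chain_id} seq {seq_index}")

    @property
    def axial_span(self) -> float:
        z = self.sites.axial_coord.values
        return float(z.max() - z.min())

    def crosslinked_pairs(self) -> set[tuple[int, int]]:
        pairs = set()
        h = self.sites.helix_id.values
        for xl in self.crosslinks:
            a, b = int(h[xl.donor]), int(h[xl.acceptor])
            pairs.add((min(a, b), max(a, b)))
        return pairs


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------

_HELICAL_X = "PASLERVQDN"
_TELO_POOL = "SQDEGLTVANY"


def planted_redox_positions(config: FibrilConfig) -> dict[str, list[int]]:
    """Tyr/Phe/Met positions planted around the crosslink acceptor sites.

    These are the positions the synthetic sequences (and the default MSA
    enrichment) carry, emulating the aromatic clusters observed around
    collagen crosslinks.
    """
    rules = config.crosslink_rules
    out: dict[str, list[int]] = {"Y": [], "F": [], "M": []}
    for acceptor in (rules.acceptor_n, rules.acceptor_c):
        for cls, offsets in (("Y", (2, 5)), ("F", (-2, -5)), ("M", (7,))):
            for off in offsets:
                pos = acceptor + off
                if 1 <= pos <= config.chain_length:
                    out[cls].append(pos)
    for cls in out:
        out[cls] = sorted(set(out[cls]))
    return out


def synthetic_chain_sequences(
    config: FibrilConfig, seed: int = 0
) -> dict[str, str]:
    """Deterministic synthetic α1/α2 chain sequences for a config.

    Gly-X-Y helical repeats with hydroxyproline (``p``) in Y positions,
    non-repetitive telopeptides, lysine donors (``K``) at the telopeptide
    crosslink positions, hydroxylysine acceptors (``k``) at the helical
    acceptor positions, and a planted Tyr/Phe/Met cluster around each
    acceptor.  Synthetic stand-ins for the rat COL1A1/COL1A2 chains: only
    the features the pipeline measures (crosslink chemistry, redox-residue
    clustering, Gly-X-Y texture) are reproduced.
    """
    L = config.chain_length
    rules = config.crosslink_rules
    planted = planted_redox_positions(config)
    families = sorted(set(config.chain_composition))
    sequences = {}
    for fam_i, fam in enumerate(families):
        rng = np.random.default_rng(seed * 7919 + fam_i)
        seq = [""] * (L + 1)  # 1-based
        helix_start = config.telo_n[1] + 1
        helix_end = config.telo_c[0] - 1
        for s in range(1, L + 1):
            if s < helix_start or s > helix_end:
                seq[s] = _TELO_POOL[rng.integers(len(_TELO_POOL))]
            else:
                frame = (s - helix_start) % 3
                if frame == 0:
                    seq[s] = "G"
                elif frame == 1:
                    seq[s] = _HELICAL_X[rng.integers(len(_HELICAL_X))]
                else:
                    seq[s] = "p" if rng.random() < 0.45 else "A"
        seq[rules.donor_n] = "K"
        seq[rules.donor_c] = "K"
        seq[rules.acceptor_n] = "k"
        seq[rules.acceptor_c] = "k"
        for cls, positions in planted.items():
            for pos in positions:
                # keep the Gly frame intact where possible
                if helix_start <= pos <= helix_end and (pos - helix_start) % 3 == 0:
                    pos += 1
                if 1 <= pos <= L:
                    seq[pos] = cls
        sequences[fam] = "".join(seq[1:])
    return sequences


# ---------------------------------------------------------------------------
# build operations
# ---------------------------------------------------------------------------

def build_topology(
    config: FibrilConfig, sequences: Mapping[str, str]
) -> FibrilTopology:
    """Lay out all residue sites of a one-D-period fibril segment.

    Deterministic: no randomness.  Residues outside the axial window
    ``[0, D]`` are truncated; gap/overlap labels are assigned against
    ``overlap_fraction`` and telopeptide ranges override both.
    """
    for fam in config.chain_composition:
        if fam not in sequences:
            raise StructuralError(f"no sequence provided for chain family {fam!r}")
        if len(sequences[fam]) < config.chain_length:
            raise StructuralError(
                f"sequence for chain {fam!r} is shorter than the required "
                f"span ({len(sequences[fam])} < {config.chain_length})"
            )
    S = config.stagger_residues
    rise = config.axial_rise
    overlap_z = config.overlap_fraction * config.D + 1e-9

    helix_ids, chain_ids, seq_idx, residues, axials, regions, fams = (
        [], [], [], [], [], [], []
    )
    for h in range(config.n_helices):
        t = config.stagger_class(h)
        for c, fam in enumerate(config.chain_composition):
            seq = sequences[fam]
            for s in range(1, config.chain_length + 1):
                m = s - 1 - S * t + config.z_offset_residues
                if m < 0 or m > S:
                    continue
                z = m * rise
                if config.is_telopeptide(s):
                    region = "telopeptide"
                elif z <= overlap_z:
                    region = "overlap"
                else:
                    region = "gap"
                helix_ids.append(h)
                chain_ids.append(c)
                seq_idx.append(s)
                residues.append(seq[s - 1])
                axials.append(z)
                regions.append(region)
                fams.append(fam)

    sites = pd.DataFrame(
        {
            "helix_id": np.array(helix_ids, dtype=np.int64),
            "chain_id": np.array(chain_ids, dtype=np.int64),
            "seq_index": np.array(seq_idx, dtype=np.int64),
            "residue": residues,
            "axial_coord": np.array(axials, dtype=float),
            "region": regions,
            "family": fams,
        }
    )

    # backbone bonds: consecutive seq_index within one chain of one helix
    order = np.lexsort(
        (sites.seq_index.values, sites.chain_id.values, sites.helix_id.values)
    )
    h_ = sites.helix_id.values[order]
    c_ = sites.chain_id.values[order]
    s_ = sites.seq_index.values[order]
    consec = (
        (h_[1:] == h_[:-1]) & (c_[1:] == c_[:-1]) & (s_[1:] == s_[:-1] + 1)
    )
    bi = order[:-1][consec].astype(np.int64)
    bj = order[1:][consec].astype(np.int64)
    bonds = BondedTopology(bi, bj, np.array([BACKBONE] * len(bi), dtype=object))

    return FibrilTopology(
        config=config,
        sites=sites,
        crosslinks=[],
        bonds=bonds,
        sequences=dict(sequences),
    )


def place_crosslinks(topology: FibrilTopology) -> FibrilTopology:
    """Populate HLKNL crosslinks on a built topology (idempotent).

    For each adjacency pair whose donor and acceptor sites both lie inside
    the segment, exactly one N-terminal and one C-terminal crosslink is
    created; crosslink bonds are appended to the bond table.
    """
    config = topology.config
    rules = config.crosslink_rules

    for fam in set(config.chain_composition):
        seq = topology.sequences[fam]
        for label, pos in (
            ("N-donor", rules.donor_n),
            ("N-acceptor", rules.acceptor_n),
            ("C-donor", rules.donor_c),
            ("C-acceptor", rules.acceptor_c),
        ):
            if seq[pos - 1] not in _LYSINE_LIKE:
                raise ValidationError(
                    f"crosslink rule {label} points at residue "
                    f"{seq[pos - 1]!r} (position {pos}, chain {fam}); "
                    "expected Lys (K) or hydroxylysine (k)"
                )

    # drop any previously placed crosslinks (idempotence)
    keep = topology.bonds.kind != CROSSLINK
    bonds = BondedTopology(
        topology.bonds.i[keep], topology.bonds.j[keep], topology.bonds.kind[keep]
    )
    crosslinks: list[Crosslink] = []

    def find(helix, chain, seq_index):
        try:
            return topology.site_index(helix, chain, seq_index)
        except KeyError:
            return None

    xl_id = 0
    for a, b in config.adjacency:
        for terminal, donor_pos, acceptor_pos in (
            ("N", rules.donor_n, rules.acceptor_n),
            ("C", rules.donor_c, rules.acceptor_c),
        ):
            placed = None
            for dh, ah in ((a, b), (b, a)):
                d = find(dh, rules.donor_chain, donor_pos)
                acc = find(ah, rules.acceptor_chain, acceptor_pos)
                if d is None or acc is None:
                    continue
                dz = abs(
                    topology.sites.axial_coord.values[d]
                    - topology.sites.axial_coord.values[acc]
                )
                if dz > rules.axial_cutoff:
                    continue
                placed = (d, acc)
                break
            if placed is not None:
                d, acc = placed
                crosslinks.append(
                    Crosslink(id=xl_id, kind="HLKNL", terminal=terminal,
                              donor=d, acceptor=acc)
                )
                bonds.append(d, acc, CROSSLINK)
                xl_id += 1

    return FibrilTopology(
        config=config,
        sites=topology.sites,
        crosslinks=crosslinks,
        bonds=bonds,
        sequences=topology.sequences,
    )


def build_fibril(
    config: FibrilConfig | None = None,
    sequences: Mapping[str, str] | None = None,
) -> FibrilTopology:
    """Convenience: default config + synthetic sequences + crosslinks."""
    config = config or FibrilConfig()
    sequences = sequences or synthetic_chain_sequences(config)
    return place_crosslinks(build_topology(config, sequences))


def linear_chain_topology(
    n_residues: int,
    spacing: float | None = None,
    residue: str = "A",
) -> FibrilTopology:
    """A single free bead-spring chain (no crosslinks), for oracle runs."""
    if n_residues < 2:
        raise ConfigurationError("a chain needs at least two residues")
    spacing = spacing if spacing is not None else 67.0 / 234.0
    config = FibrilConfig(
        n_helices=1,
        D=(n_residues - 1) * spacing,
        stagger_residues=n_residues - 1,
        axial_rise=spacing,
        chain_length=n_residues,
        z_offset_residues=0,
        overlap_fraction=0.5,
        chain_composition=("X", "X", "X"),
        adjacency=(),
        telo_n=(1, 1),
        telo_c=(n_residues, n_residues),
    )
    sites = pd.DataFrame(
        {
            "helix_id": np.zeros(n_residues, dtype=np.int64),
            "chain_id": np.zeros(n_residues, dtype=np.int64),
            "seq_index": np.arange(1, n_residues + 1, dtype=np.int64),
            "residue": [residue] * n_residues,
            "axial_coord": np.arange(n_residues, dtype=float) * spacing,
            "region": ["overlap"] * n_residues,
            "family": ["X"] * n_residues,
        }
    )
    bi = np.arange(n_residues - 1, dtype=np.int64)
    bonds = BondedTopology(bi, bi + 1, np.array([BACKBONE] * len(bi), dtype=object))
    return FibrilTopology(
        config=config, sites=sites, crosslinks=[], bonds=bonds,
        sequences={"X": residue * n_residues},
    )


def linear_chain_coords(topology: FibrilTopology) -> np.ndarray:
    """Straight-line bead coordinates on the z axis (for chain oracles)."""
    n = topology.n_sites
    coords = np.zeros((n, 3))
    coords[:, 2] = topology.sites.axial_coord.values
    return coords


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def _hex_lattice(n: int, spacing: float) -> np.ndarray:
    """First n points of a triangular lattice, sorted radially (deterministic)."""
    pts = []
    r = int(math.ceil(math.sqrt(n))) + 2
    for u in range(-r, r + 1):
        for v in range(-r, r + 1):
            x = (u + 0.5 * v) * spacing
            y = (math.sqrt(3) / 2.0) * v * spacing
            pts.append((x * x + y * y, math.atan2(y, x), x, y))
    pts.sort()
    return np.array([(x, y) for _, _, x, y in pts[:n]], dtype=float)


def generate_coordinates(
    topology: FibrilTopology,
    seed: int = 0,
    jitter: float = 0.0,
    minor_radius: float = 0.25,
    pitch: float = 3.0,
) -> np.ndarray:
    """One bead per residue: three chains wound about each helix axis.

    Helix axes sit on a triangular lattice with the configured spacing; the
    bead z-coordinate equals the site's axial coordinate (exactly, for
    ``jitter=0``).  Crosslink donor beads — telopeptide residues, hence
    conformationally free — are repositioned laterally next to their
    acceptor so every donor–acceptor 3-D distance is within the axial
    cutoff.  Seeded jitter is optional and applied to all coordinates.
    """
    config = topology.config
    if config.lattice_spacing <= 0:
        raise ConfigurationError("lattice_spacing must be positive")
    axes = _hex_lattice(config.n_helices, config.lattice_spacing)

    h = topology.sites.helix_id.values
    c = topology.sites.chain_id.values
    z = topology.sites.axial_coord.values
    phase = 2.0 * np.pi * (z / pitch) + 2.0 * np.pi * c / 3.0
    coords = np.empty((topology.n_sites, 3), dtype=float)
    coords[:, 0] = axes[h, 0] + minor_radius * np.cos(phase)
    coords[:, 1] = axes[h, 1] + minor_radius * np.sin(phase)
    coords[:, 2] = z

    cutoff = config.crosslink_rules.axial_cutoff
    for xl in topology.crosslinks:
        acc = coords[xl.acceptor]
        donor_axis = axes[h[xl.donor]]
        lateral = donor_axis - acc[:2]
        norm = np.linalg.norm(lateral)
        direction = lateral / norm if norm > 1e-12 else np.array([1.0, 0.0])
        dz = z[xl.donor] - acc[2]
        max_lat = math.sqrt(max(cutoff**2 - dz**2, 0.0)) * 0.6
        coords[xl.donor, 0] = acc[0] + direction[0] * max_lat
        coords[xl.donor, 1] = acc[1] + direction[1] * max_lat
        coords[xl.donor, 2] = z[xl.donor]

    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    return coords


# ---------------------------------------------------------------------------
# structure / table I/O
# ---------------------------------------------------------------------------

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"

#: one-letter (incl. lowercase modified) -> PDB residue name
_RES3 = {
    "G": "GLY", "A": "ALA", "S": "SER", "T": "THR", "C": "CYS", "V": "VAL",
    "L": "LEU", "I": "ILE", "M": "MET", "P": "PRO", "F": "PHE", "Y": "TYR",
    "W": "TRP", "D": "ASP", "E": "GLU", "N": "ASN", "Q": "GLN", "H": "HIS",
    "K": "LYS", "R": "ARG", "p": "HYP", "k": "LYZ",
}


def write_structure(
    coords: np.ndarray, topology: FibrilTopology, out_prefix: str | Path
) -> dict[str, Path]:
    """Write a CA-only PDB (crosslinks as CONECT) plus TSV topology tables.

    Emits ``<prefix>.pdb``, ``<prefix>.sites.tsv``, ``<prefix>.bonds.tsv``
    and ``<prefix>.crosslinks.tsv``.  Coordinates are written in Å (PDB
    convention; internal nm are multiplied by 10).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_sites, 3):
        raise StructuralError(
            f"coordinate count {coords.shape} does not match "
            f"site count {topology.n_sites}"
        )
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    n = topology.n_sites
    arr = struc.AtomArray(n)
    arr.coord = coords * 10.0  # nm -> Å
    h = topology.sites.helix_id.values
    c = topology.sites.chain_id.values
    chain_serial = h * len(topology.config.chain_composition) + c
    arr.chain_id = np.array(
        [_CHAIN_ALPHABET[k % len(_CHAIN_ALPHABET)] for k in chain_serial]
    )
    arr.res_id = topology.sites.seq_index.values
    arr.res_name = np.array(
        [_RES3.get(r, "UNK") for r in topology.sites.residue.values]
    )
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    xl_bonds = np.array(
        [[xl.donor, xl.acceptor, 0] for xl in topology.crosslinks], dtype=np.uint32
    ).reshape(-1, 3)
    arr.bonds = struc.BondList(n, xl_bonds)

    pdb_path = out_prefix.with_suffix(".pdb")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(pdb_path)

    sites_path = out_prefix.parent / (out_prefix.name + ".sites.tsv")
    topology.sites.to_csv(sites_path, sep="\t", index_label="site")

    bonds_path = out_prefix.parent / (out_prefix.name + ".bonds.tsv")
    pd.DataFrame(
        {"i": topology.bonds.i, "j": topology.bonds.j, "kind": topology.bonds.kind}
    ).to_csv(bonds_path, sep="\t", index=False)

    xl_path = out_prefix.parent / (out_prefix.name + ".crosslinks.tsv")
    pd.DataFrame(
        [
            {
                "id": xl.id, "kind": xl.kind, "terminal": xl.terminal,
                "donor": xl.donor, "acceptor": xl.acceptor,
            }
            for xl in topology.crosslinks
        ],
        columns=["id", "kind", "terminal", "donor", "acceptor"],
    ).to_csv(xl_path, sep="\t", index=False)

    return {"pdb": pdb_path, "sites": sites_path, "bonds": bonds_path,
            "crosslinks": xl_path}


def read_structure(out_prefix: str | Path):
    """Read back what :func:`write_structure` wrote.

    Returns ``(coords_nm, sites, bonds, crosslinks)`` where the last three
    are DataFrames.  Round trip preserves site and crosslink counts exactly.
    """
    from biotite.structure.io.pdb import PDBFile

    out_prefix = Path(out_prefix)
    pdb = PDBFile.read(out_prefix.with_suffix(".pdb"))
    if pdb.get_model_count() > 0:
        arr = pdb.get_structure(model=1)
        coords = arr.coord / 10.0
    else:
        coords = np.empty((0, 3), dtype=float)
    sites = pd.read_csv(
        out_prefix.parent / (out_prefix.name + ".sites.tsv"), sep="\t", index_col=0
    )
    bonds = pd.read_csv(out_prefix.parent / (out_prefix.name + ".bonds.tsv"), sep="\t")
    crosslinks = pd.read_csv(
        out_prefix.parent / (out_prefix.name + ".crosslinks.tsv"), sep="\t"
    )
    return coords, sites, bonds, crosslinks
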