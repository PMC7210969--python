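"""Force distribution analysis of bead-spring pulling trajectories.

Time-averaged scalar pairwise bond forces ``F_ij`` are recomputed from the
trajectory via Hooke's law, ``F = k (|r_i - r_j| - r0)``, signed with
tension positive and compression negative.  Only bonded terms (backbone
and crosslink bonds) enter.  Windowed per-pair profiles average the
backbone forces of the chain that receives each crosslink (its acceptor
chain) over sliding windows of ``w`` consecutive residues (step 1), with
the crosslink bond force entering the windows that cover the acceptor
position; the aggregate profile is the mean with standard errors across
the crosslink-connected pairs, not across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .fibril_topology import BACKBONE, CROSSLINK, FibrilTopology
from .synthetic_data import Trajectory


@dataclass
class PairwiseForceTable:
    """Per-bond mean signed scalar force (nN, tension positive).

    ``entries`` columns: i, j, kind, F (mean), sd, se, n_frames.  The value
    for (i, j) is by construction the value for (j, i) (Newton pairing of a
    central bond force).
    """

    entries: pd.DataFrame
    topology: FibrilTopology
    loading_label: str = ""

    def force(self, i: int, j: int) -> float:
        a, b = min(i, j), max(i, j)
        sel = self.entries[(self.entries.i == a) & (self.entries.j == b)]
        if len(sel) == 0:
            raise KeyError(f"no bonded pair ({i}, {j})")
        return float(sel.F.iloc[0])


def compute_pairwise_forces(
    trajectory: Trajectory,
    topology: FibrilTopology | None = None,
    include_equilibration: bool = False,
) -> PairwiseForceTable:
    """Time-average the scalar bond forces over the retained frames."""
    topology = topology or trajectory.topology
    if trajectory.frames.shape[1] != topology.n_sites:
        raise StructuralError(
            "trajectory frame width does not match topology site count"
        )
    bonds = topology.bonds
    if len(bonds) != len(trajectory.bond_rest_lengths):
        raise StructuralError("bond table does not match trajectory bond data")
    if np.max(np.concatenate([bonds.i, bonds.j])) >= topology.n_sites:
        raise StructuralError("bond references a missing site")
    frames = (
        trajectory.frames if include_equilibration else trajectory.retained_frames
    )
    if frames.shape[0] == 0:
        raise StructuralError("no retained frames to average over")

    d = frames[:, bonds.i, :] - frames[:, bonds.j, :]  # (F, B, 3)
    lengths = np.sqrt(np.einsum("fbc,fbc->fb", d, d))
    forces = trajectory.bond_spring_constants[None, :] * (
        lengths - trajectory.bond_rest_lengths[None, :]
    )
    mean = forces.mean(axis=0)
    sd = forces.std(axis=0, ddof=1) if forces.shape[0] > 1 else np.zeros_like(mean)
    n = forces.shape[0]
    lo = np.minimum(bonds.i, bonds.j)
    hi = np.maximum(bonds.i, bonds.j)
    entries = pd.DataFrame(
        {
            "i": lo,
            "j": hi,
            "kind": bonds.kind,
            "F": mean,
            "sd": sd,
            "se": sd / np.sqrt(n),
            "n_frames": n,
        }
    )
    return PairwiseForceTable(entries=entries, topology=topology)


def diff_force_tables(
    loaded: PairwiseForceTable, control: PairwiseForceTable
) -> PairwiseForceTable:
    """Entrywise loaded-minus-control difference of bond force means.

    Standard deviations combine in quadrature.  Both tables must share the
    same bond set.
    """
    a = loaded.entries.sort_values(["i", "j"]).reset_index(drop=True)
    b = control.entries.sort_values(["i", "j"]).reset_index(drop=True)
    if len(a) != len(b) or not (
        (a.i.values == b.i.values).all() and (a.j.values == b.j.values).all()
    ):
        only_a = set(zip(a.i, a.j)) - set(zip(b.i, b.j))
        only_b = set(zip(b.i, b.j)) - set(zip(a.i, a.j))
        raise StructuralError(
            f"mismatched bond sets; loaded-only={sorted(only_a)[:5]} "
            f"control-only={sorted(only_b)[:5]}"
        )
    out = a.copy()
    out["F"] = a.F.values - b.F.values
    out["sd"] = np.sqrt(a.sd.values**2 + b.sd.values**2)
    out["se"] = np.sqrt(a.se.values**2 + b.se.values**2)
    out["n_frames"] = np.minimum(a.n_frames.values, b.n_frames.values)
    return PairwiseForceTable(
        entries=out, topology=loaded.topology, loading_label="difference"
    )


# ---------------------------------------------------------------------------
# windowed profiles
# ---------------------------------------------------------------------------

def sliding_window_mean(
    positions: np.ndarray, values: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` in windows of ``w`` consecutive residue positions,
    advancing one residue at a time.

    ``positions`` are (possibly repeated) integer residue positions; a
    window starting at ``p`` covers ``[p, p + w)``.  Returns
    ``(window_centers, window_means)``; windows with no members are
    skipped.
    """
    if w < 1:
        raise ValidationError("window length must be >= 1")
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    lo, hi = int(positions.min()), int(positions.max())
    if hi - lo + 1 < w:
        raise ValidationError("window longer than the available span")
    centers, means = [], []
    for start in range(lo, hi - w + 2):
        mask = (positions >= start) & (positions < start + w)
        if mask.any():
            centers.append(start + (w - 1) / 2.0)
            means.append(values[mask].mean())
    return np.array(centers), np.array(means)


@dataclass
class TerminalProfile:
    """Windowed force series of all pairs sharing a crosslink terminal."""

    centers: np.ndarray          # window centers, residue seq_index units
    per_pair: np.ndarray         # (n_pairs, n_windows)
    pair_labels: list[tuple[int, int]]
    crosslink_positions: np.ndarray  # acceptor seq_index per pair
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean = self.per_pair.mean(axis=0)
        n = self.per_pair.shape[0]
        self.sem = (
            self.per_pair.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.zeros_like(self.mean)
        )


@dataclass
class ForceProfile:
    window_length: int
    terminals: dict[str, TerminalProfile]


def windowed_profile(
    table: PairwiseForceTable,
    topology: FibrilTopology | None = None,
    w: int = 10,
) -> ForceProfile:
    """Windowed per-pair force profiles along crosslink acceptor chains.

    For each crosslink, the backbone bonds of the chain carrying the
    acceptor are windowed over ``w`` consecutive residues (each bond
    attributed to its lower seq_index); the crosslink bond force enters at
    the acceptor's position.  Series are grouped by terminal (N/C) and
    aggregated as mean ± sem over the pairs.
    """
    topology = topology or table.topology
    if w < 1:
        raise ValidationError("window length must be >= 1")
    if not topology.crosslinks:
        raise ValidationError("topology has no crosslinks to profile")

    sites = topology.sites
    entries = table.entries
    helix = sites.helix_id.values
    chain = sites.chain_id.values
    seq = sites.seq_index.values

    by_terminal: dict[str, list] = {"N": [], "C": []}
    for xl in topology.crosslinks:
        ah, ac = int(helix[xl.acceptor]), int(chain[xl.acceptor])
        dh = int(helix[xl.donor])
        on_chain = (helix[entries.i.values] == ah) & (chain[entries.i.values] == ac) \
            & (helix[entries.j.values] == ah) & (chain[entries.j.values] == ac) \
            & (entries.kind.values == BACKBONE)
        sub = entries[on_chain]
        positions = np.minimum(seq[sub.i.values], seq[sub.j.values])
        values = sub.F.values
        # the crosslink bond itself, at the acceptor position
        xl_rows = entries[
            (entries.kind == CROSSLINK)
            & (np.minimum(entries.i, entries.j) == min(xl.donor, xl.acceptor))
            & (np.maximum(entries.i, entries.j) == max(xl.donor, xl.acceptor))
        ]
        positions = np.concatenate([positions, [seq[xl.acceptor]] * len(xl_rows)])
        values = np.concatenate([values, xl_rows.F.values])
        centers, means = sliding_window_mean(positions, values, w)
        by_terminal[xl.terminal].append(
            ((min(dh, ah), max(dh, ah)), seq[xl.acceptor], centers, means)
        )

    terminals = {}
    for terminal, series in by_terminal.items():
        if not series:
            continue
        ref_centers = series[0][2]
        rows, labels, xpos = [], [], []
        for label, acc_pos, centers, means in series:
            if len(centers) != len(ref_centers) or not np.allclose(
                centers, ref_centers
            ):
                raise StructuralError(
                    "pair profiles are not aligned; acceptor chains differ in span"
                )
            rows.append(means)
            labels.append(label)
            xpos.append(acc_pos)
        terminals[terminal] = TerminalProfile(
            centers=ref_centers,
            per_pair=np.vstack(rows),
            pair_labels=labels,
            crosslink_positions=np.array(xpos),
        )
    return ForceProfile(window_length=w, terminals=terminals)


def locate_maxima(profile: ForceProfile, terminal: str) -> pd.DataFrame:
    """Window centers ranked by descending aggregate mean force.

    Ties are broken by ascending residue position.  Each row carries the
    center's distance (in residues) to the nearest crosslink acceptor
    position of that terminal.
    """
    if terminal not in profile.terminals:
        raise ValidationError(f"profile has no terminal {terminal!r}")
    tp = profile.terminals[terminal]
    if len(tp.centers) == 0:
        raise ValidationError("empty profile")
    order = np.lexsort((tp.centers, -tp.mean))
    centers = tp.centers[order]
    dist = np.min(
        np.abs(centers[:, None] - tp.crosslink_positions[None, :]), axis=1
    )
    return pd.DataFrame(
        {
            "center": centers,
            "mean_force": tp.mean[order],
            "distance_to_crosslink": dist,
        }
    )
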