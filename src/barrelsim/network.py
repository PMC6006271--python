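"""Fixed random connectivity of the TC -> FS -> RS circuit.

Connections are random but fixed: wiring is sampled once per experiment
and reused across all trials and both adaptation states.  TC cells are
partitioned into 8 direction groups of 30 and RS cells into 8 direction
domains of 20; the TC->RS connection probability falls off with the
angular offset between the TC group's and the RS domain's preferred
directions (0.7, 0.5, 0.3, 0.15, 0.1 at offsets 0..180 degrees).  FS->RS
connectivity is complete, and RS->RS connectivity is all-to-all without
autapses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Union

import numpy as np

from .params import DIRECTIONS, OFFSETS, PROJECTIONS, ModelParams

#: Sub-stream labels for seed derivation.  Wiring and stimulus sampling use
#: disjoint spawn keys of the master seed so trials are reproducible
#: independently of wiring.
WIRING_STREAM = 0
STIMULUS_STREAM = 1


class InvalidDirectionError(ValueError):
    """A direction or offset outside the 45-degree grid."""


def angular_offset(dir_a: float, dir_b: float) -> int:
    """Minimal absolute circular difference between two direction labels.

    Both directions must be multiples of 45 degrees in [0, 360); the result
    is in {0, 45, 90, 135, 180}.
    """
    for d in (dir_a, dir_b):
        if d % 45 != 0 or not (0 <= d < 360):
            raise InvalidDirectionError(
                f"direction {d!r} is not a multiple of 45 in [0, 360)"
            )
    diff = abs(int(dir_a) - int(dir_b)) % 360
    return min(diff, 360 - diff)


def tc_rs_connection_prob(offset: int, params: ModelParams | None = None) -> float:
    """TC->RS connection probability for a TC-group/RS-domain offset."""
    table = (params or ModelParams()).p_tc_rs_by_offset
    if offset not in table:
        raise InvalidDirectionError(f"offset {offset!r} not in {sorted(table)}")
    return table[offset]


def mean_tc_rs_connection_prob(params: ModelParams | None = None) -> float:
    """Unweighted mean of the five offset-specific TC->RS probabilities.

    This is the 0.35 "average connection probability" convention; note that
    240 * 0.35 = 84 while the group-weighted expected in-degree is 81
    (offsets 45..135 occur twice among the eight groups but the average
    here weights each distinct offset once).
    """
    table = (params or ModelParams()).p_tc_rs_by_offset
    return float(np.mean([table[o] for o in OFFSETS]))


def expected_tc_rs_in_degree(params: ModelParams | None = None) -> float:
    """Group-weighted expected TC in-degree of an RS cell (81 by default)."""
    p = params or ModelParams()
    table = p.p_tc_rs_by_offset
    total = 0.0
    for d in DIRECTIONS:
        total += p.tc_group_size * table[angular_offset(d, 0)]
    return total


@dataclass
class Wiring:
    """Fixed adjacency of the five projections plus direction labels.

    ``presyn[proj][j]`` lists the presynaptic indices of postsynaptic cell
    ``j`` for each projection in :data:`~barrelsim.params.PROJECTIONS`.
    Dense boolean matrices (``conn[proj]``, shape ``(n_pre, n_post)``) are
    kept alongside for the integrator.
    """

    tc_group_of: np.ndarray  # (n_tc,) preferred direction in degrees
    rs_domain_of: np.ndarray  # (n_rs,) domain direction in degrees
    conn: Dict[str, np.ndarray]  # projection -> (n_pre, n_post) bool
    seed: int

    @property
    def presyn(self) -> Dict[str, List[np.ndarray]]:
        return {
            proj: [np.flatnonzero(mat[:, j]) for j in range(mat.shape[1])]
            for proj, mat in self.conn.items()
        }

    def in_degrees(self, proj: str) -> np.ndarray:
        return self.conn[proj].sum(axis=0)

    def rs_cells_in_domain(self, domain_deg: int) -> np.ndarray:
        return np.flatnonzero(self.rs_domain_of == domain_deg)

    def tc_cells_in_group(self, group_deg: int) -> np.ndarray:
        return np.flatnonzero(self.tc_group_of == group_deg)

    # ---- serialization -------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        doc = {
            "seed": int(self.seed),
            "tc_group_of": self.tc_group_of.tolist(),
            "rs_domain_of": self.rs_domain_of.tolist(),
            "presyn": {
                proj: [lst.tolist() for lst in per_post]
                for proj, per_post in self.presyn.items()
            },
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "Wiring":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        tc_group_of = np.asarray(doc["tc_group_of"], dtype=int)
        rs_domain_of = np.asarray(doc["rs_domain_of"], dtype=int)
        n_by_kind = {
            "tc": len(tc_group_of),
            "fs": len(doc["presyn"]["fs->fs"]),
            "rs": len(rs_domain_of),
        }
        conn: Dict[str, np.ndarray] = {}
        for proj, per_post in doc["presyn"].items():
            n_post = len(per_post)
            n_pre = n_by_kind[proj.split("->")[0]]
            mat = np.zeros((n_pre, n_post), dtype=bool)
            for j, pres in enumerate(per_post):
                mat[pres, j] = True
            conn[proj] = mat
        return cls(
            tc_group_of=tc_group_of,
            rs_domain_of=rs_domain_of,
            conn=conn,
            seed=int(doc["seed"]),
        )


def _bernoulli(rng: np.random.Generator, p: float, shape, no_self: bool = False):
    mat = rng.random(shape) < p
    if no_self:
        np.fill_diagonal(mat, False)
    return mat


def build_wiring(params: ModelParams, seed: int) -> Wiring:
    """Sample the fixed random wiring of the circuit.

    Deterministic given ``seed`` (a dedicated wiring sub-stream of the
    master seed is used, so stimulus draws never perturb wiring).
    Autapses are excluded in fs->fs and rs->rs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(WIRING_STREAM,)))

    tc_group_of = np.repeat(DIRECTIONS, params.tc_group_size)
    rs_domain_of = np.repeat(DIRECTIONS, params.rs_domain_size)

    conn: Dict[str, np.ndarray] = {}
    conn["tc->fs"] = _bernoulli(rng, params.p_tc_fs, (params.n_tc, params.n_fs))

    p_rs = np.empty((params.n_tc, params.n_rs))
    for i in range(params.n_tc):
        for j in range(params.n_rs):
            off = angular_offset(tc_group_of[i], rs_domain_of[j])
            p_rs[i, j] = params.p_tc_rs_by_offset[off]
    conn["tc->rs"] = rng.random((params.n_tc, params.n_rs)) < p_rs

    conn["fs->fs"] = _bernoulli(rng, params.p_fs_fs, (params.n_fs, params.n_fs), no_self=True)
    conn["fs->rs"] = _bernoulli(rng, params.p_fs_rs, (params.n_fs, params.n_rs))
    rs_rs = np.ones((params.n_rs, params.n_rs), dtype=bool)
    np.fill_diagonal(rs_rs, False)
    conn["rs->rs"] = rs_rs

    assert set(conn) == set(PROJECTIONS)
    return Wiring(
        tc_group_of=np.asarray(tc_group_of),
        rs_domain_of=np.asarray(rs_domain_of),
        conn=conn,
        seed=seed,
    )
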