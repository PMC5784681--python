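"""Synthetic ground-truth structures and degraded contact predictions.

Everything downstream of contact prediction is testable against toy
targets built here: idealized helix bundles, strand sandwiches or mixed
topologies with known coordinates, their true Cβ-Cβ contact maps, and
"predicted" contact sets of controlled precision (true contacts mixed
with uniformly drawn decoy pairs whose confidence is sampled below the
true range, so confidence-ranked subsets are precision-enriched the way
real predictors' lists are).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from contactfold.io_formats import Contact, Model, SecondaryStructure, SequenceRecord
from contactfold.folding import place_cb

# ideal alpha-helix Calpha trace: 2.3 Å radius, 1.5 Å rise, 100°/residue
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
# extended strand: 3.3 Å rise with ±1.0 Å zigzag
STRAND_RISE = 3.3
STRAND_ZIG = 1.0

_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """A stated toy world: topology, size, and contact-set quality."""

    topology: str = "helix_bundle"  # helix_bundle | strand_sandwich | mixed
    n_segments: int = 3
    segment_len: int = 14
    linker_len: int = 3
    spacing: float = 8.2
    precision: float = 1.0
    n_contacts: int | None = None
    min_sep: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.topology not in ("helix_bundle", "strand_sandwich", "mixed"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0.0 < self.precision <= 1.0):
            raise ValueError("precision must lie in (0, 1]")
        if self.n_segments < 1 or self.segment_len < 4 or self.linker_len < 1:
            raise ValueError("invalid fixture dimensions")

    @property
    def L(self) -> int:
        return self.n_segments * self.segment_len + (self.n_segments - 1) * self.linker_len

    @property
    def segment_states(self) -> list[str]:
        if self.topology == "helix_bundle":
            return ["H"] * self.n_segments
        if self.topology == "strand_sandwich":
            return ["E"] * self.n_segments
        return ["H" if k % 2 == 0 else "E" for k in range(self.n_segments)]


def _helix_trace(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack(
        [
            HELIX_RADIUS * np.cos(HELIX_TWIST * t),
            HELIX_RADIUS * np.sin(HELIX_TWIST * t),
            HELIX_RISE * t,
        ],
        axis=1,
    )


def _strand_trace(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack(
        [STRAND_ZIG * np.where(t % 2 == 0, 1.0, -1.0), np.zeros(n), STRAND_RISE * t],
        axis=1,
    )


def _linker(p_from: np.ndarray, p_to: np.ndarray, n_res: int, out_dir: np.ndarray,
            bond: float = 3.8) -> np.ndarray:
    """n_res coil residues joining two anchors as an arc over the segment
    ends.

    Interior points interpolate the anchor chord, all displaced off it by
    the same height h in alternating directions (a blend of out_dir and
    the lateral normal), which clears the segment bodies; h is solved so
    interior bonds are exactly `bond` Å and end bonds stay within the
    chain-geometry window [3.0, 4.6].
    """
    nb = n_res + 1
    gap = p_to - p_from
    D = float(np.linalg.norm(gap))
    if D / nb > bond - 1e-9:
        raise ValueError(f"linker of {n_res} residues cannot span {D:.1f} Å")
    u = gap / D
    v = np.cross(u, out_dir)
    if np.linalg.norm(v) < 1e-6:
        v = np.array([0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)

    def _proj_unit(w):
        w = w - np.dot(w, u) * u
        return w / np.linalg.norm(w)

    o1 = _proj_unit(2.0 * out_dir + v)
    o2 = _proj_unit(2.0 * out_dir - v)
    c = np.linalg.norm(o1 - o2)
    h = math.sqrt(max(bond**2 - (D / nb) ** 2, 0.0) / max(c * c, 1e-9))
    end_bond = math.hypot(D / nb, h)
    if not (3.0 <= end_bond <= 4.6):
        raise ValueError(f"linker geometry infeasible: end bond {end_bond:.2f} Å")
    pts = np.empty((n_res, 3))
    for m in range(1, n_res + 1):
        pts[m - 1] = p_from + (m / nb) * gap + h * (o1 if m % 2 == 1 else o2)
    return pts


def make_native(spec: FixtureSpec) -> tuple[Model, SecondaryStructure]:
    """Deterministic idealized structure plus its matching H/E/C string.

    Segments run antiparallel at `spacing` Å lateral separation; linkers
    arc over the segment ends with exact 3.8 Å bonds.  Raises if the
    packing produces a steric violation (nonbonded Cα pair < 4.0 Å).
    """
    states = spec.segment_states
    pieces: list[np.ndarray] = []
    ss_parts: list[str] = []
    prev_end = None
    for k, state in enumerate(states):
        n = spec.segment_len
        trace = _helix_trace(n) if state == "H" else _strand_trace(n)
        if k % 2 == 1:  # antiparallel: flip the chain direction in z
            trace = trace[::-1].copy()
        trace[:, 0] += k * spec.spacing
        if prev_end is not None:
            # align the connecting ends vertically, then arc over them
            trace[:, 2] += prev_end[2] - trace[0, 2]
            grows_up = trace[-1, 2] >= trace[0, 2]
            out_dir = np.array([0.0, 0.0, -1.0 if grows_up else 1.0])
            pieces.append(_linker(prev_end, trace[0], spec.linker_len, out_dir))
            ss_parts.append("C" * spec.linker_len)
        pieces.append(trace)
        ss_parts.append(state * n)
        prev_end = trace[-1]
    ca = np.vstack(pieces)
    rng = np.random.default_rng(spec.seed)
    residues = "".join(rng.choice(list(_AA_POOL), size=spec.L))
    seq = SequenceRecord(id=f"{spec.topology}_{spec.n_segments}x{spec.segment_len}", residues=residues)
    cb = place_cb(ca, residues)
    model = Model(sequence=seq, ca=ca, cb=cb, label="native")
    _check_sterics(ca)
    return model, SecondaryStructure(states="".join(ss_parts))


def _check_sterics(ca: np.ndarray, min_dist: float = 4.0) -> None:
    from scipy.spatial.distance import pdist

    L = ca.shape[0]
    if L < 3:
        return
    i, j = np.triu_indices(L, k=1)
    d = pdist(ca)
    nb = d[(j - i) >= 2]
    if nb.min() < min_dist:
        raise ValueError(
            f"fixture packing infeasible: min nonbonded Cα distance {nb.min():.2f} Å"
        )


def true_contacts(model: Model, threshold: float = 8.0, min_sep: int = 6) -> list[Contact]:
    """All Cβ-Cβ pairs under `threshold` Å with sequence separation >= min_sep.

    Confidence is distance-informative: prob = 1 - d / (2·threshold), so
    sorting by prob ranks closer pairs first.
    """
    if threshold <= 0:
        return []
    L = len(model)
    diff = model.cb[:, None, :] - model.cb[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    i, j = np.triu_indices(L, k=min_sep)
    keep = D[i, j] <= threshold
    out = [
        Contact(i=int(a) + 1, j=int(b) + 1, lower=0.0, upper=threshold,
                prob=float(1.0 - D[a, b] / (2.0 * threshold)))
        for a, b in zip(i[keep], j[keep])
    ]
    return sorted(out, key=lambda c: (-c.prob, c.i, c.j))


def degrade_contacts(true: list[Contact], spec: FixtureSpec) -> list[Contact]:
    """Emit a "predicted" contact set of requested size and precision.

    round(precision · n_contacts) members are sampled from the true set
    (keeping their confidences); the rest are decoy pairs drawn uniformly
    from non-contact pairs at >= min_sep separation, with confidences
    sampled strictly below the selected true contacts' range.
    """
    if not true:
        raise ValueError("no true contacts to degrade")
    rng = np.random.default_rng(spec.seed)
    n_contacts = spec.n_contacts if spec.n_contacts is not None else len(true)
    n_true = int(round(spec.precision * n_contacts))
    n_decoy = n_contacts - n_true
    if n_true > len(true):
        raise ValueError(
            f"requested {n_true} true contacts but only {len(true)} exist"
        )
    chosen_idx = np.sort(rng.choice(len(true), size=n_true, replace=False))
    chosen = [true[k] for k in chosen_idx]
    L = spec.L
    true_pairs = {(c.i, c.j) for c in true}
    candidates = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + spec.min_sep, L + 1)
        if (i, j) not in true_pairs
    ]
    if n_decoy > len(candidates):
        raise ValueError("n_contacts exceeds the number of available residue pairs")
    decoy_idx = rng.choice(len(candidates), size=n_decoy, replace=False)
    floor_prob = min(c.prob for c in chosen) if chosen else 0.5
    decoys = [
        Contact(i=candidates[k][0], j=candidates[k][1], lower=0.0, upper=8.0,
                prob=float(rng.uniform(0.02, max(0.03, 0.95 * floor_prob))))
        for k in decoy_idx
    ]
    return sorted(chosen + decoys, key=lambda c: (-c.prob, c.i, c.j))
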