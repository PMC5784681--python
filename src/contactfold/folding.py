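"""Coarse-grained restrained folding by simulated annealing.

Models are two-bead chains: one Cα per residue plus a virtual Cβ riding
1.53 Å from its Cα (glycine has none; its Cβ coincides with Cα).  The
total energy is

    E = E_contact + E_ss + E_bond + E_clash

where contact and secondary-structure terms are soft-square distance
restraints, E_bond = Σ k_b (|Cα_i - Cα_{i+1}| - b0)² keeps the chain
connected, and E_clash = Σ k_c max(0, d_c - |Cα_i - Cα_j|)² over
|i - j| >= 2 keeps it self-avoiding.

The Cβ beads are not free particles: they are re-derived from the local
Cα frame after every move, which makes the Cβ-Cβ contact energy sensitive
to handedness (a mirror-image fold scores visibly worse), the classic
failure mode of purely distance-based reconstruction.

The optimizer is Metropolis annealing over single-residue Gaussian moves
interleaved with line-searched gradient-descent sweeps.  The first half
of the schedule works on the pure square-error surface (the soft-square
with r_sw -> ∞), whose long-range pull drives the initial collapse; the
second half works on the true tapered surface.  The best chain-feasible
state seen is kept, scored by the true energy, so the returned model
never has higher energy than the starting chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from contactfold.io_formats import Model, SecondaryStructure, SequenceRecord
from contactfold.restraints import (
    DistanceRestraint,
    pairing_restraint,
)

BOND_MIN = 3.0  # hard feasibility window for consecutive Cα-Cα (Å)
BOND_MAX = 4.6


@dataclass
class FoldConfig:
    """Folding protocol parameters.

    n_steps is the total number of Metropolis moves (None = 5000·L, chosen
    at fold time); temperatures follow a geometric schedule from t_start
    to t_end over n_blocks blocks, with one gradient-descent sweep per
    block.
    """

    n_steps: int | None = None
    t_start: float = 10.0
    t_end: float = 0.05
    step_scale: float = 2.0
    seed: int = 0
    bond_length: float = 3.8
    bond_k: float = 10.0
    clash_dist: float = 4.0
    clash_k: float = 10.0
    cb_dist: float = 1.53
    stage2_enabled: bool = True
    stage2_violation_cutoff: float = 2.0
    n_blocks: int = 40
    sweep_iters: int = 30

    def __post_init__(self):
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if not (BOND_MIN <= self.bond_length <= BOND_MAX):
            raise ValueError(f"bond_length must lie in [{BOND_MIN}, {BOND_MAX}]")
        for name in ("step_scale", "bond_k", "clash_dist", "clash_k", "cb_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FoldConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class EnergyBreakdown:
    e_contact: float
    e_ss: float
    e_bond: float
    e_clash: float

    @property
    def e_total(self) -> float:
        return self.e_contact + self.e_ss + self.e_bond + self.e_clash


def place_cb_directions(ca: np.ndarray) -> np.ndarray:
    """Unit Cβ directions from the local Cα frame.

    For interior residues the direction tilts off the bisector of the two
    backbone bonds toward the local normal (roughly tetrahedral); chain
    ends copy their neighbour's frame.  Degenerate (collinear) frames fall
    back to a deterministic perpendicular.
    """
    L = ca.shape[0]
    dirs = np.zeros((L, 3))
    if L == 1:
        dirs[0] = (1.0, 0.0, 0.0)
        return dirs
    b1 = ca[1:-1] - ca[:-2]
    b2 = ca[1:-1] - ca[2:]
    u1 = _unit_rows(b1)
    u2 = _unit_rows(b2)
    bis = u1 + u2
    nrm = np.cross(u1, u2)
    bis = _unit_rows_with_fallback(bis, u1)
    nrm = _unit_rows_with_fallback(nrm, u1, roll=True)
    if L > 2:
        dirs[1:-1] = _unit_rows(0.8165 * bis + 0.5774 * nrm)
        dirs[0] = dirs[1]
        dirs[-1] = dirs[-2]
    else:
        u = _unit_rows(ca[1:2] - ca[0:1])[0]
        perp = _perpendicular(u)
        dirs[0] = perp
        dirs[1] = perp
    return dirs


def place_cb(ca: np.ndarray, residues: str, cb_dist: float = 1.53) -> np.ndarray:
    """Cβ coordinates for a Cα trace; glycine Cβ equals Cα."""
    dirs = place_cb_directions(ca)
    is_gly = np.array([aa == "G" for aa in residues])
    cb = ca + cb_dist * dirs
    cb[is_gly] = ca[is_gly]
    return cb


def _unit_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=1, keepdims=True)
    return v / np.where(n < 1e-12, 1.0, n)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    e = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = e - np.dot(e, u) * u
    return p / np.linalg.norm(p)


def _unit_rows_with_fallback(v: np.ndarray, ref: np.ndarray, roll: bool = False) -> np.ndarray:
    n = np.linalg.norm(v, axis=1)
    out = v / np.where(n < 1e-8, 1.0, n)[:, None]
    bad = np.nonzero(n < 1e-8)[0]
    for k in bad:
        p = _perpendicular(ref[k])
        out[k] = np.cross(ref[k], p) if roll else p
    return out


class _RestraintTable:
    """Flat array view of a restraint list for vectorized evaluation."""

    def __init__(self, restraints: list[DistanceRestraint], L: int):
        n = len(restraints)
        self.n = n
        self.L = L
        self.restraints = list(restraints)
        self.ri = np.array([r.i - 1 for r in restraints], dtype=np.intp)
        self.rj = np.array([r.j - 1 for r in restraints], dtype=np.intp)
        if n and (self.ri.min() < 0 or self.rj.max() >= L):
            raise IndexError("restraint index out of range for chain length")
        self.cb_i = np.array([r.atom_i == "CB" for r in restraints])
        self.cb_j = np.array([r.atom_j == "CB" for r in restraints])
        get = lambda attr: np.array([getattr(r.params, attr) for r in restraints], dtype=float)
        self.lo = get("d") - get("d_minus")
        self.hi = get("d") + get("d_plus")
        self.switch = np.array([r.params.switch_distance for r in restraints])
        self.a = get("a")
        self.b = get("b")
        self.weff = np.array([r.params.weight for r in restraints])
        self.exp = get("exp")
        self.softexp = get("softexp")
        self.is_contact = np.array([r.origin == "contact" for r in restraints])

    def distances(self, ca: np.ndarray, off: np.ndarray, rows=None) -> np.ndarray:
        if rows is None:
            ri, rj, cbi, cbj = self.ri, self.rj, self.cb_i, self.cb_j
        else:
            ri, rj = self.ri[rows], self.rj[rows]
            cbi, cbj = self.cb_i[rows], self.cb_j[rows]
        xi = ca[ri] + off[ri] * cbi[:, None]
        xj = ca[rj] + off[rj] * cbj[:, None]
        return np.linalg.norm(xi - xj, axis=1)

    def energies(self, R: np.ndarray, rows=None, pure_square: bool = False) -> np.ndarray:
        if rows is None:
            lo, hi, sw = self.lo, self.hi, self.switch
            a, b, w = self.a, self.b, self.weff
            ex, sx = self.exp, self.softexp
        else:
            lo, hi, sw = self.lo[rows], self.hi[rows], self.switch[rows]
            a, b, w = self.a[rows], self.b[rows], self.weff[rows]
            ex, sx = self.exp[rows], self.softexp[rows]
        delta = np.where(R >= hi, R - hi, np.where(R < lo, lo - R, 0.0))
        if pure_square:
            return w * delta**ex
        soft = R >= sw
        safe = np.where(soft, delta, 1.0)
        return w * np.where(soft, a + b / safe**sx, delta**ex)

    def grad_dR(self, R: np.ndarray, pure_square: bool = False) -> np.ndarray:
        """dE/dR per row; pure_square ignores the taper (r_sw -> ∞)."""
        delta = np.where(R >= self.hi, R - self.hi, np.where(R < self.lo, self.lo - R, 0.0))
        sign = np.where(R >= self.hi, 1.0, np.where(R < self.lo, -1.0, 0.0))
        safe = np.where(delta > 0, delta, 1.0)
        g_sq = self.weff * self.exp * safe ** (self.exp - 1.0) * sign
        if pure_square:
            return np.where(delta > 0, g_sq, 0.0)
        soft = R >= self.switch
        g_soft = -self.weff * self.softexp * self.b / safe ** (self.softexp + 1.0)
        return np.where(delta > 0, np.where(soft, g_soft, g_sq), 0.0)


def _bond_energy(ca: np.ndarray, cfg: FoldConfig) -> float:
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    return float(cfg.bond_k * np.sum((d - cfg.bond_length) ** 2))


def _clash_energy(ca: np.ndarray, cfg: FoldConfig) -> float:
    from scipy.spatial.distance import pdist

    L = ca.shape[0]
    if L < 3:
        return 0.0
    d = pdist(ca)
    # condensed index mask for |i - j| >= 2, built once per length
    mask = _nonbonded_mask(L)
    viol = np.maximum(0.0, cfg.clash_dist - d[mask])
    return float(cfg.clash_k * np.sum(viol**2))


_MASK_CACHE: dict[int, np.ndarray] = {}


def _nonbonded_mask(L: int) -> np.ndarray:
    m = _MASK_CACHE.get(L)
    if m is None:
        i, j = np.triu_indices(L, k=1)
        m = (j - i) >= 2
        _MASK_CACHE[L] = m
    return m


def _energy_parts(tab: _RestraintTable, ca: np.ndarray, off: np.ndarray, cfg: FoldConfig,
                  pure_square: bool = False):
    if tab.n:
        e_rows = tab.energies(tab.distances(ca, off), pure_square=pure_square)
        e_contact = float(e_rows[tab.is_contact].sum())
        e_ss = float(e_rows[~tab.is_contact].sum())
    else:
        e_contact = e_ss = 0.0
    return EnergyBreakdown(
        e_contact=e_contact,
        e_ss=e_ss,
        e_bond=_bond_energy(ca, cfg),
        e_clash=_clash_energy(ca, cfg),
    )


def total_energy(
    model: Model, restraints: list[DistanceRestraint], config: FoldConfig | None = None
) -> EnergyBreakdown:
    """Energy breakdown of a model under a restraint list.

    Contact/ss terms are evaluated at the model's own Cα/Cβ coordinates.
    """
    cfg = config or FoldConfig()
    tab = _RestraintTable(restraints, len(model))
    off = model.cb - model.ca
    return _energy_parts(tab, model.ca, off, cfg)


def initialize_chain(
    L: int, seed: int, config: FoldConfig | None = None, sequence: SequenceRecord | None = None
) -> Model:
    """Self-avoiding random-walk chain: Cα steps of bond_length, no
    nonbonded Cα pair closer than clash_dist; deterministic per seed."""
    if L < 2:
        raise ValueError("chain needs at least 2 residues")
    cfg = config or FoldConfig()
    rng = np.random.default_rng(seed)
    ca = np.zeros((L, 3))
    direction = _random_unit(rng)
    ca[1] = ca[0] + cfg.bond_length * direction
    i = 2
    stuck = 0
    while i < L:
        placed = False
        for _ in range(200):
            # correlated direction keeps the walk chain-like, not a blob
            trial_dir = _unit_rows((direction + 0.8 * _random_unit(rng)).reshape(1, 3))[0]
            trial = ca[i - 1] + cfg.bond_length * trial_dir
            dists = np.linalg.norm(ca[: i - 1] - trial, axis=1)
            if dists.min() >= cfg.clash_dist:
                ca[i] = trial
                direction = trial_dir
                placed = True
                break
        if placed:
            i += 1
            stuck = 0
        else:
            i = max(2, i - 3)  # backtrack out of a dead end
            stuck += 1
            if stuck > 50:
                raise RuntimeError("self-avoiding walk failed to complete")
    residues = sequence.residues if sequence is not None else "A" * L
    seq = sequence or SequenceRecord(id=f"chain{L}", residues=residues)
    cb = place_cb(ca, residues, cfg.cb_dist)
    return Model(sequence=seq, ca=ca, cb=cb, label=f"init_seed{seed}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chain_feasible(ca: np.ndarray) -> bool:
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    return bool((d >= BOND_MIN).all() and (d <= BOND_MAX).all())


def _derive_off(ca: np.ndarray, is_gly: np.ndarray, cb_dist: float) -> np.ndarray:
    """Frame-derived Cβ offsets; zero for glycine."""
    off = cb_dist * place_cb_directions(ca)
    off[is_gly] = 0.0
    return off


def _surface_parts(tab, ca, cfg, is_gly, pure_square=False):
    """Energy breakdown with Cβ re-derived from the current backbone."""
    off = _derive_off(ca, is_gly, cfg.cb_dist)
    return _energy_parts(tab, ca, off, cfg, pure_square)


def _gradient(tab, ca, off, cfg, pure_square):
    """Gradient of the total energy w.r.t. Cα positions.

    Forces on a Cβ are applied to its parent Cα (the bead rides the
    residue; the frame-rotation coupling is ignored, which only affects
    the proposal direction — acceptance re-derives Cβ exactly).
    """
    L = ca.shape[0]
    g_ca = np.zeros((L, 3))
    if tab.n:
        xi = ca[tab.ri] + off[tab.ri] * tab.cb_i[:, None]
        xj = ca[tab.rj] + off[tab.rj] * tab.cb_j[:, None]
        dvec = xi - xj
        R = np.linalg.norm(dvec, axis=1)
        safeR = np.where(R < 1e-9, 1.0, R)
        f = (tab.grad_dR(R, pure_square) / safeR)[:, None] * dvec  # dE/dxi
        np.add.at(g_ca, tab.ri, f)
        np.add.at(g_ca, tab.rj, -f)
    # bonds
    dvec = ca[1:] - ca[:-1]
    d = np.linalg.norm(dvec, axis=1)
    fb = (2.0 * cfg.bond_k * (d - cfg.bond_length) / np.where(d < 1e-9, 1.0, d))[:, None] * dvec
    g_ca[1:] += fb
    g_ca[:-1] -= fb
    # clashes (pairwise matrix; L is small)
    diff = ca[:, None, :] - ca[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    viol = (sep >= 2) & (D < cfg.clash_dist)
    coef = np.where(viol, -2.0 * cfg.clash_k * (cfg.clash_dist - D) / np.where(D < 1e-9, 1.0, D), 0.0)
    g_ca += np.einsum("ij,ijk->ik", coef, diff)
    return g_ca


def _descend(tab, ca, cfg, is_gly, iters, pure_square, lr):
    """Line-searched gradient descent on the Cα trace.

    Proposal direction and acceptance both use the same surface: the pure
    square-error surrogate during the collapse phase, the true tapered
    energy afterwards.  Returns the improved trace, its energy on that
    surface, and the adapted step length.
    """
    e = _surface_parts(tab, ca, cfg, is_gly, pure_square).e_total
    fails = 0
    for _ in range(iters):
        off = _derive_off(ca, is_gly, cfg.cb_dist)
        g_ca = _gradient(tab, ca, off, cfg, pure_square)
        gmax = np.abs(g_ca).max()
        if gmax < 1e-12:
            break
        scale = 1.0 / max(gmax, 1.0)
        improved = False
        for step in (2.0 * lr, lr, 0.5 * lr, 0.2 * lr):
            trial_ca = ca - step * scale * g_ca
            e_trial = _surface_parts(tab, trial_ca, cfg, is_gly, pure_square).e_total
            if e_trial < e - 1e-12:
                ca, e = trial_ca, e_trial
                lr = min(step * 1.5, 4.0)
                improved = True
                break
        if not improved:
            fails += 1
            lr = max(lr * 0.5, 1e-3)
            if fails >= 3:
                break
    return ca, e, lr


def fold(
    L: int,
    restraints: list[DistanceRestraint],
    config: FoldConfig | None = None,
    sequence: SequenceRecord | None = None,
    init: Model | None = None,
    label: str = "",
) -> Model:
    """Fold a chain of length L against a restraint list.

    Runs Metropolis-annealed single-residue moves interleaved with
    gradient sweeps starting from a self-avoiding random walk (or from
    ``init``'s Cα trace when given).  Deterministic for a fixed config
    seed; the returned model's total energy never exceeds the starting
    energy.
    """
    cfg = config or FoldConfig()
    if sequence is not None and len(sequence) != L:
        raise ValueError("sequence length does not match L")
    tab = _RestraintTable(restraints, L)
    rng = np.random.default_rng(cfg.seed)
    if init is not None:
        seq = sequence or init.sequence
        ca = init.ca.copy()
    else:
        start = initialize_chain(L, seed=cfg.seed, config=cfg, sequence=sequence)
        seq = start.sequence
        ca = start.ca
    is_gly = np.array([aa == "G" for aa in seq.residues])

    n_steps = cfg.n_steps if cfg.n_steps is not None else 5000 * L
    n_blocks = max(1, min(cfg.n_blocks, n_steps))
    moves_per_block = n_steps // n_blocks
    temps = np.geomspace(cfg.t_start, cfg.t_end, n_blocks)

    best_ca = ca.copy()
    best_e = _surface_parts(tab, ca, cfg, is_gly).e_total
    lr = 0.5

    for block in range(n_blocks):
        # continuation: collapse on the pure square-error surface first,
        # then refine on the true tapered surface
        pure_square = block < n_blocks // 2
        T = temps[block]
        sigma = cfg.step_scale * math.sqrt(T / cfg.t_start)
        e_current = _surface_parts(tab, ca, cfg, is_gly, pure_square).e_total
        e_current = _metropolis_block(
            tab, ca, cfg, rng, moves_per_block, T, sigma, e_current, is_gly, pure_square
        )
        ca, e_current, lr = _descend(tab, ca, cfg, is_gly, cfg.sweep_iters, pure_square, lr)
        e_true = e_current if not pure_square else _surface_parts(tab, ca, cfg, is_gly).e_total
        if e_true < best_e and _chain_feasible(ca):
            best_ca, best_e = ca.copy(), e_true
    # polishing sweep on the true energy surface
    ca, e_current, lr = _descend(tab, best_ca.copy(), cfg, is_gly, 2 * cfg.sweep_iters, False, lr)
    if e_current < best_e and _chain_feasible(ca):
        best_ca, best_e = ca, e_current
    cb = best_ca + _derive_off(best_ca, is_gly, cfg.cb_dist)
    return Model(sequence=seq, ca=best_ca, cb=cb, label=label or f"seed{cfg.seed}")


def _metropolis_block(tab, ca, cfg, rng, n_moves, T, sigma, e_current, is_gly, pure_square=False):
    """In-place Metropolis single-residue moves; returns the updated
    running energy on the active (surrogate or true) surface."""
    L = ca.shape[0]
    for _ in range(n_moves):
        k = int(rng.integers(L))
        disp = rng.normal(0.0, sigma, 3)
        saved = ca[k].copy()
        ca[k] = saved + disp
        e_new = _surface_parts(tab, ca, cfg, is_gly, pure_square).e_total
        dE = e_new - e_current
        if dE <= 0 or rng.random() < math.exp(-dE / T):
            e_current = e_new
        else:
            ca[k] = saved
    return e_current


def stage2_refine(
    stage1_model: Model,
    restraints: list[DistanceRestraint],
    ss: SecondaryStructure,
    config: FoldConfig,
) -> tuple[list[DistanceRestraint], Model]:
    """Second-stage refinement around a first-stage model.

    Contact restraints violated beyond ``stage2_violation_cutoff`` in the
    stage-1 model are dropped (they contradict the consensus fold);
    Cα pairing restraints are added for strand residues from different
    strand runs found close (< 5.5 Å) in the stage-1 model; then the model
    is refolded from its stage-1 coordinates under the edited set.
    """
    ca, cb = stage1_model.ca, stage1_model.cb
    kept: list[DistanceRestraint] = []
    for r in restraints:
        if r.origin != "contact":
            kept.append(r)
            continue
        xi = cb[r.i - 1] if r.atom_i == "CB" else ca[r.i - 1]
        xj = cb[r.j - 1] if r.atom_j == "CB" else ca[r.j - 1]
        R = float(np.linalg.norm(xi - xj))
        hi = r.params.d + r.params.d_plus
        lo = r.params.d - r.params.d_minus
        delta = R - hi if R >= hi else (lo - R if R < lo else 0.0)
        if delta <= config.stage2_violation_cutoff:
            kept.append(r)
    run_id = np.full(len(ss), -1)
    for rid, (start, end) in enumerate(ss.runs("E")):
        run_id[start - 1 : end] = rid
    strand_res = np.nonzero(run_id >= 0)[0]
    existing = {(r.i, r.j, r.origin) for r in kept}
    for ai in range(len(strand_res)):
        for bi in range(ai + 1, len(strand_res)):
            p, q = int(strand_res[ai]), int(strand_res[bi])
            if run_id[p] == run_id[q]:
                continue
            if np.linalg.norm(ca[p] - ca[q]) < 5.5:
                r = pairing_restraint(p + 1, q + 1)
                if (r.i, r.j, r.origin) not in existing:
                    kept.append(r)
                    existing.add((r.i, r.j, r.origin))
    cfg2 = replace(
        config,
        seed=config.seed + 500_000,
        n_steps=max(1, (config.n_steps if config.n_steps is not None else 5000 * len(stage1_model)) // 2),
        t_start=max(config.t_end, config.t_start / 10.0),
    )
    refined = fold(
        len(stage1_model), kept, cfg2, sequence=stage1_model.sequence,
        init=stage1_model, label=stage1_model.label + "+stage2",
    )
    return kept, refined
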