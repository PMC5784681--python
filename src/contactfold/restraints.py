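"""Soft-square distance restraint energy.

The contact energy is a flat-bottomed square error that tapers to a
bounded constant beyond a switching width ``r_sw``:

    E(R) = min(ceil, w) * { Δ^exp                 if R <  d + d_plus + r_sw
                          { a + b / Δ^softexp     if R >= d + d_plus + r_sw

where the violation Δ is

    Δ(R) = R - (d + d_plus)   if R >= d + d_plus
         = (d - d_minus) - R  if R <  d - d_minus
         = 0                  otherwise

so energy and gradient vanish on the well [d - d_minus, d + d_plus].
``a`` and ``b`` are fixed at run time so that the two branches agree in
value and slope at Δ = r_sw; grossly violated restraints therefore stop
dominating the gradient instead of growing quadratically forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from contactfold.io_formats import Contact, SecondaryStructure

#: defaults for contacts predicted at < 8 Å Cβ-Cβ: zero-error well [3.5, 8.0] Å
CONTACT_D = 3.6
CONTACT_D_MINUS = 0.1
CONTACT_D_PLUS = 4.4
DEFAULT_R_SW = 1.8

# idealized secondary-structure geometry (Å)
HELIX_I_IP4_CA = 6.2
HELIX_SLACK = 0.3
STRAND_I_IP2_CA = 6.7
STRAND_SLACK = 0.4
PAIRING_CA = 5.2
PAIRING_SLACK = 0.5


def compute_smoothing_constants(
    r_sw: float, exp: float = 2.0, softexp: float = 2.0
) -> tuple[float, float]:
    """Constants (a, b) making the energy smooth at Δ = r_sw.

    Solves value continuity  r_sw^exp = a + b / r_sw^softexp  together with
    slope continuity  exp * r_sw^(exp-1) = -softexp * b / r_sw^(softexp+1):

        b = -(exp / softexp) * r_sw^(exp + softexp)
        a = (1 + exp / softexp) * r_sw^exp

    For exp = softexp = 2 this is a = 2 r_sw², b = -r_sw⁴.
    """
    if r_sw <= 0 or exp <= 0 or softexp <= 0:
        raise ValueError("r_sw, exp and softexp must all be positive")
    b = -(exp / softexp) * r_sw ** (exp + softexp)
    a = (1.0 + exp / softexp) * r_sw**exp
    return a, b


@dataclass(frozen=True)
class RestraintParams:
    """All symbols of the soft-square energy for one restraint.

    d, d_minus, d_plus define the zero-error well [d - d_minus, d + d_plus]
    (Å); r_sw is the switching width (Å) beyond which the square error
    tapers; ceil caps the per-pair weight and w is the per-pair weight.
    a and b are derived, never set by hand.
    """

    d: float = CONTACT_D
    d_minus: float = CONTACT_D_MINUS
    d_plus: float = CONTACT_D_PLUS
    r_sw: float = DEFAULT_R_SW
    exp: float = 2.0
    softexp: float = 2.0
    ceil: float = 1000.0
    w: float = 1.0
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self):
        if min(self.d_minus, self.d_plus) < 0 or min(self.ceil, self.w) <= 0:
            raise ValueError("invalid restraint parameters")
        a, b = compute_smoothing_constants(self.r_sw, self.exp, self.softexp)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def weight(self) -> float:
        return min(self.ceil, self.w)

    @property
    def switch_distance(self) -> float:
        """R beyond which the tapered branch applies."""
        return self.d + self.d_plus + self.r_sw


@dataclass(frozen=True)
class DistanceRestraint:
    """A distance restraint between two atoms of residues i < j (1-based)."""

    i: int
    j: int
    atom_i: str  # "CA" or "CB"
    atom_j: str
    params: RestraintParams
    origin: str  # contact | ss_helix | ss_strand | ss_pairing

    def __post_init__(self):
        if not (1 <= self.i < self.j):
            raise ValueError(f"restraint indices must satisfy 1 <= i < j, got ({self.i}, {self.j})")
        if self.atom_i not in ("CA", "CB") or self.atom_j not in ("CA", "CB"):
            raise ValueError("atoms must be CA or CB")


def contact_error(R, params: RestraintParams):
    """Violation Δ (Å) of the flat-bottomed well; scalar or array."""
    R = np.asarray(R, dtype=float)
    hi = params.d + params.d_plus
    lo = params.d - params.d_minus
    delta = np.where(R >= hi, R - hi, np.where(R < lo, lo - R, 0.0))
    return delta if delta.ndim else float(delta)


def contact_energy(R, params: RestraintParams):
    """Soft-square energy at distance R (scalar or array).

    The taper applies only to upper-bound violations (R beyond
    d + d_plus + r_sw); lower-bound violations stay purely quadratic.
    """
    R = np.asarray(R, dtype=float)
    delta = np.asarray(contact_error(R, params))
    soft = R >= params.switch_distance
    square = params.weight * delta**params.exp
    energy = np.where(
        soft,
        params.weight
        * (params.a + params.b / np.where(soft, delta, 1.0) ** params.softexp),
        square,
    )
    return energy if energy.ndim else float(energy)


def contact_energy_gradient(R, params: RestraintParams):
    """dE/dR of the soft-square energy (scalar or array).

    Exact except at the two well edges and the switch point, where the
    one-sided derivative of the active branch is returned.
    """
    R = np.asarray(R, dtype=float)
    delta = np.asarray(contact_error(R, params))
    hi = params.d + params.d_plus
    lo = params.d - params.d_minus
    soft = R >= params.switch_distance
    safe = np.where(delta > 0, delta, 1.0)
    grad = np.zeros_like(R)
    upper_sq = (R >= hi) & ~soft
    grad = np.where(upper_sq, params.weight * params.exp * safe ** (params.exp - 1), grad)
    grad = np.where(
        soft,
        -params.weight * params.softexp * params.b / safe ** (params.softexp + 1),
        grad,
    )
    grad = np.where(R < lo, -params.weight * params.exp * safe ** (params.exp - 1), grad)
    return grad if grad.ndim else float(grad)


def build_contact_restraints(
    contacts: list[Contact], sequence=None, params: RestraintParams | None = None
) -> list[DistanceRestraint]:
    """One Cβ-Cβ soft-square restraint per predicted contact.

    Glycine has no Cβ, so its end of the restraint falls back to Cα
    (the model stores glycine Cβ at the Cα position anyway; using CA makes
    the convention explicit in the restraint list).
    """
    if params is None:
        params = RestraintParams()
    residues = sequence.residues if sequence is not None else None

    def atom_for(idx: int) -> str:
        if residues is not None and residues[idx - 1] == "G":
            return "CA"
        return "CB"

    return [
        DistanceRestraint(
            i=c.i, j=c.j, atom_i=atom_for(c.i), atom_j=atom_for(c.j),
            params=params, origin="contact",
        )
        for c in contacts
    ]


def build_ss_restraints(ss: SecondaryStructure) -> list[DistanceRestraint]:
    """Idealized-geometry Cα restraints from a 3-state string.

    Helix runs of length >= 4 get (i, i+4) restraints at 6.2 ± 0.3 Å;
    strand runs of length >= 3 get (i, i+2) restraints at 6.7 ± 0.4 Å.
    Coil contributes nothing.
    """
    helix_params = RestraintParams(d=HELIX_I_IP4_CA, d_minus=HELIX_SLACK, d_plus=HELIX_SLACK)
    strand_params = RestraintParams(d=STRAND_I_IP2_CA, d_minus=STRAND_SLACK, d_plus=STRAND_SLACK)
    out: list[DistanceRestraint] = []
    for start, end in ss.runs("H"):
        if end - start + 1 >= 4:
            for i in range(start, end - 3):
                out.append(
                    DistanceRestraint(i=i, j=i + 4, atom_i="CA", atom_j="CA",
                                      params=helix_params, origin="ss_helix")
                )
    for start, end in ss.runs("E"):
        if end - start + 1 >= 3:
            for i in range(start, end - 1):
                out.append(
                    DistanceRestraint(i=i, j=i + 2, atom_i="CA", atom_j="CA",
                                      params=strand_params, origin="ss_strand")
                )
    return out


def pairing_restraint(i: int, j: int) -> DistanceRestraint:
    """A Cα-Cα beta-pairing restraint at 5.2 ± 0.5 Å."""
    return DistanceRestraint(
        i=min(i, j), j=max(i, j), atom_i="CA", atom_j="CA",
        params=RestraintParams(d=PAIRING_CA, d_minus=PAIRING_SLACK, d_plus=PAIRING_SLACK),
        origin="ss_pairing",
    )


def write_restraints_tsv(restraints: list[DistanceRestraint], path) -> None:
    """Human-readable restraint dump for debugging."""
    with open(path, "w") as fh:
        fh.write("i\tj\tatom_i\tatom_j\td\td_minus\td_plus\torigin\n")
        for r in restraints:
            fh.write(
                f"{r.i}\t{r.j}\t{r.atom_i}\t{r.atom_j}\t"
                f"{r.params.d:g}\t{r.params.d_minus:g}\t{r.params.d_plus:g}\t{r.origin}\n"
            )
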