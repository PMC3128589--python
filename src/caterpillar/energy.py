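"""The three caterpillar energy terms and their total.

The potential has three parts, all in reduced model units with k_B = 1:

* a residue-residue pair term: a continuous square well between CA-centred
  spheres, switched off smoothly at the interaction range r_cut, with depths
  taken from a 20x20 contact-energy matrix;
* a directional backbone hydrogen bond: a 10-12 Lennard-Jones radial form in
  the O...H distance, modulated by the C'-O-H and O-H-N angles so that only
  near-linear geometries bond;
* an optional solvation penalty, linear in a hydrophobic residue's shortfall
  of CA contacts below the burial threshold n_c.

Self-avoidance is a hard core between non-consecutive CA spheres handled as
an infinite-energy sentinel (rejection), never as a steep potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import ChainGeometry

__all__ = [
    "AA_ALPHABET",
    "AA_INDEX",
    "ModelParameters",
    "EnergyBreakdown",
    "pair_energy",
    "switching_function",
    "hbond_energy",
    "hbond_total",
    "solvation_energy",
    "total_energy",
    "calibrate_hb_balance",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def _default_eps():
    from .fixtures import load_tables

    return load_tables()[0]


def _default_hydropathy():
    from .fixtures import load_tables

    return load_tables()[1]


@dataclass
class ModelParameters:
    """All energy constants of the model (reduced units, lengths in Angstrom).

    pair_scale multiplies the contact term and is the knob used to balance
    the pair and hydrogen-bond contributions per particle on a reference
    structure (see calibrate_hb_balance).  r_cut doubles as the contact
    radius used by the solvation term's burial count.
    """

    eps_matrix: np.ndarray = field(default_factory=_default_eps)
    pair_scale: float = 0.05
    r_cut: float = 12.0
    switch_width: float = 0.5
    sphere_radius: float = 2.4
    hb_epsilon: float = 3.0
    hb_sigma: float = 2.0
    hb_cutoff: float = 4.5
    hb_angle_exponent: int = 4
    solvation_scale: float = 1.0
    n_contact_threshold: int = 24
    hydropathy: np.ndarray = field(default_factory=_default_hydropathy)

    def __post_init__(self):
        self.eps_matrix = np.asarray(self.eps_matrix, dtype=np.float64)
        self.hydropathy = np.asarray(self.hydropathy, dtype=np.float64)
        if self.eps_matrix.shape != (20, 20):
            raise ValueError("eps_matrix must be 20x20")
        if not np.array_equal(self.eps_matrix, self.eps_matrix.T):
            raise ValueError("eps_matrix must be exactly symmetric")
        if self.hydropathy.shape != (20,):
            raise ValueError("hydropathy must be a 20-vector")
        if not self.r_cut > 2.0 * self.sphere_radius:
            raise ValueError("r_cut must exceed the hard-core diameter")
        if self.n_contact_threshold < 0:
            raise ValueError("contact threshold must be >= 0")
        for name in ("pair_scale", "r_cut", "switch_width", "sphere_radius",
                     "hb_epsilon", "hb_sigma", "hb_cutoff", "solvation_scale"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def hard_core_distance(self) -> float:
        return 2.0 * self.sphere_radius

    def with_pair_scale(self, k: float) -> "ModelParameters":
        return replace(self, pair_scale=float(k),
                       eps_matrix=self.eps_matrix.copy(),
                       hydropathy=self.hydropathy.copy())

    def _kernel_args(self, use_solvation: bool):
        return (self.eps_matrix, self.hydropathy, self.pair_scale, self.r_cut,
                self.switch_width, self.hard_core_distance, self.hb_epsilon,
                self.hb_sigma, self.hb_cutoff, self.hb_angle_exponent,
                self.solvation_scale, self.n_contact_threshold,
                1 if use_solvation else 0)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Component-wise energy; all +inf when the hard core is violated."""

    e_pair: float
    e_hb: float
    e_solv: float
    overlap: bool = False

    @property
    def e_total(self) -> float:
        if self.overlap:
            return math.inf
        return self.e_pair + self.e_hb + self.e_solv

    @classmethod
    def overlapping(cls) -> "EnergyBreakdown":
        return cls(math.inf, math.inf, math.inf, overlap=True)


def switching_function(r, p: ModelParameters):
    """Continuous square well switch S(r) = [1 - tanh((r - r_cut)/w)] / 2."""
    r = np.asarray(r, dtype=np.float64)
    return 0.5 * (1.0 - np.tanh((r - p.r_cut) / p.switch_width))


def pair_energy(r: float, a: str, b: str, p: ModelParameters) -> float:
    """Sphere-sphere contact energy at CA separation r; +inf inside the core."""
    if not r > 0:
        raise ValueError("distance must be positive")
    if a not in AA_INDEX or b not in AA_INDEX:
        raise ValueError(f"unknown amino-acid code: {a!r}/{b!r}")
    if r < p.hard_core_distance:
        return math.inf
    return float(p.pair_scale * p.eps_matrix[AA_INDEX[a], AA_INDEX[b]]
                 * switching_function(r, p))


def hbond_energy(r_oh: float, alpha: float, beta: float, p: ModelParameters) -> float:
    """Directional 10-12 hydrogen-bond energy.

    alpha is the C'-O-H angle at the acceptor oxygen, beta the O-H-N angle at
    the donor hydrogen, both in radians.  The angular factor is
    cos^m(theta - pi) for theta > 90 deg and zero otherwise, so a perfectly
    linear bond at r = sigma scores exactly -epsilon_hb.
    """
    if not r_oh > 0:
        raise ValueError("O...H distance must be positive")
    if r_oh > p.hb_cutoff:
        return 0.0
    ca_, cb_ = math.cos(alpha), math.cos(beta)
    if ca_ >= 0.0 or cb_ >= 0.0:
        return 0.0
    m = p.hb_angle_exponent
    x = p.hb_sigma / r_oh
    lj = p.hb_epsilon * (5.0 * x**12 - 6.0 * x**10)
    return float(lj * (-ca_) ** m * (-cb_) ** m)


def hbond_total(chain: ChainGeometry, p: ModelParameters) -> float:
    """Sum of NH(i)...OC(j) bond energies over all |i-j| >= 2 donor-acceptor pairs."""
    _, eh, _, _ = _kernels.chain_energy(
        np.ascontiguousarray(chain.coords), np.zeros(chain.n_res, np.int64),
        *p._kernel_args(False))
    return float(eh)


def solvation_energy(contacts, seq, p: ModelParameters) -> float:
    """Exposure penalty k_s * sum_i max(0, h_i) * max(0, n_c - n_i) / n_c."""
    idx = _seq_indices(seq)
    contacts = np.asarray(contacts)
    if contacts.shape[0] != idx.shape[0]:
        raise ValueError("contacts and sequence length mismatch")
    if p.n_contact_threshold == 0:
        if p.solvation_scale != 0.0:
            raise ValueError("burial threshold n_c = 0 with nonzero solvation scale")
        return 0.0
    h = np.maximum(p.hydropathy[idx], 0.0)
    shortfall = np.maximum(p.n_contact_threshold - contacts, 0)
    return float(p.solvation_scale * np.sum(h * shortfall) / p.n_contact_threshold)


def _seq_indices(seq) -> np.ndarray:
    """Accept a Sequence, a string, or an integer index array."""
    if hasattr(seq, "indices"):
        return np.asarray(seq.indices, dtype=np.int64)
    if isinstance(seq, str):
        try:
            return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown amino-acid code {exc.args[0]!r}") from exc
    return np.asarray(seq, dtype=np.int64)


def total_energy(chain: ChainGeometry, seq, p: ModelParameters,
                 use_solvation: bool = False) -> EnergyBreakdown:
    """Full model energy of a conformation-sequence pair."""
    idx = _seq_indices(seq)
    if idx.shape[0] != chain.n_res:
        raise ValueError(
            f"sequence length {idx.shape[0]} != chain length {chain.n_res}")
    ep, eh, es, ov = _kernels.chain_energy(
        np.ascontiguousarray(chain.coords), idx,
        *p._kernel_args(use_solvation))
    if ov > 0.5:
        return EnergyBreakdown.overlapping()
    return EnergyBreakdown(float(ep), float(eh), float(es))


def calibrate_hb_balance(chain: ChainGeometry, seq, p: ModelParameters) -> float:
    """Pair-term scale k making |k*E_pair| = |E_hb| per particle on a reference.

    E_pair is evaluated at unit pair_scale; install the result via
    ModelParameters.with_pair_scale to balance the two contributions.
    """
    ref = total_energy(chain, seq, p.with_pair_scale(1.0))
    if ref.overlap:
        raise ValueError("reference structure has a hard-core overlap")
    if ref.e_pair == 0.0 or ref.e_hb == 0.0:
        raise ValueError("both pair and hydrogen-bond energies must be nonzero")
    return abs(ref.e_hb) / abs(ref.e_pair)
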