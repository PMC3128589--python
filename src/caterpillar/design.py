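"""Sequence design by parallel-tempering Monte Carlo on a fixed backbone.

The design state is the amino-acid sequence; the backbone (the target
structure) never moves.  A single-point-mutation move is accepted with
probability

    min{1, exp(-dE / T_design + lambda_het * d lnN_perm)}

where lnN_perm is the log of the multinomial permutation count of the
sequence's composition.  The first term drives the target's energy down;
the second rewards compositional heterogeneity, steering the ensemble away
from low-energy homopolymers that would fold to anything.  Replica exchange
across a temperature ladder keeps the search ergodic; because lambda_het is
temperature-independent it cancels exactly from the swap ratio, which
therefore involves only the energies.

Designed ensembles are summarized by the Landau free-energy surface
F(E, lnN_perm) = -T ln H over the sampled 2D histogram; sequences at its
minimum ("LowF") are the design output, and a raw-energy-minimum selector
("LowE") is provided as the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .energy import AA_ALPHABET, AA_INDEX, ModelParameters, total_energy
from .geometry import ChainGeometry, contact_counts

__all__ = [
    "Sequence",
    "SequenceSample",
    "LandauSurface",
    "DesignTarget",
    "log_multinomial",
    "mutation_step",
    "design_run",
    "landau_surface",
    "select_sequences",
    "hydropathy_profile",
]


@dataclass(frozen=True)
class Sequence:
    """Immutable amino-acid sequence with cached composition counts."""

    residues: str

    def __post_init__(self):
        bad = set(self.residues) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"unknown amino-acid code(s): {sorted(bad)}")
        if len(self.residues) == 0:
            raise ValueError("empty sequence")

    def __len__(self):
        return len(self.residues)

    def __str__(self):
        return self.residues

    @property
    def indices(self) -> np.ndarray:
        return np.array([AA_INDEX[c] for c in self.residues], dtype=np.int64)

    @property
    def counts(self) -> np.ndarray:
        out = np.zeros(20, dtype=np.int64)
        for c in self.residues:
            out[AA_INDEX[c]] += 1
        return out

    @classmethod
    def random(cls, n: int, rng: np.random.Generator,
               alphabet: str = AA_ALPHABET) -> "Sequence":
        return cls("".join(rng.choice(list(alphabet), size=n)))

    def mutated(self, pos: int, new: str) -> "Sequence":
        r = self.residues
        return Sequence(r[:pos] + new + r[pos + 1:])


def log_multinomial(seq) -> float:
    """ln[N! / (n_1! ... n_20!)] via log-gamma; exact at small N."""
    counts = seq.counts if isinstance(seq, Sequence) else np.asarray(seq)
    n = int(counts.sum())
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


@dataclass
class SequenceSample:
    """One recorded design state: sequence, its target energy, heterogeneity."""

    sequence: Sequence
    energy: float
    ln_nperm: float
    temp_index: int
    sweep: int


class DesignTarget:
    """Precomputed quantities of a fixed target backbone.

    The switch values S_ij and contact counts depend only on the structure,
    so single-mutation energy deltas reduce to one row of the eps matrix
    contracted against the precomputed S row for the mutated site.
    """

    def __init__(self, chain: ChainGeometry, params: ModelParameters,
                 use_solvation: bool = False):
        self.chain = chain
        self.params = params
        self.use_solvation = use_solvation
        n = chain.n_res
        ca = chain.ca
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        near = np.triu(d < params.hard_core_distance, k=2)
        if near.any():
            i, j = np.argwhere(near)[0]
            raise ValueError(
                f"target has a hard-core overlap between residues {i} and {j}")
        s = 0.5 * (1.0 - np.tanh((d - params.r_cut) / params.switch_width))
        mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
        self.switch = np.where(mask, s, 0.0)
        self.contacts = contact_counts(chain, params.r_cut)
        # hydrogen bonds are sequence-independent: a constant energy offset
        zero_seq = np.zeros(n, dtype=np.int64)
        _, e_hb, _, _ = _kernels.chain_energy(
            np.ascontiguousarray(chain.coords), zero_seq,
            *params._kernel_args(False))
        self.e_hb = float(e_hb)
        self.n_res = n

    def pair_energy(self, idx: np.ndarray) -> float:
        eps_seq = self.params.eps_matrix[np.ix_(idx, idx)]
        return float(self.params.pair_scale * 0.5 * np.sum(eps_seq * self.switch))

    def solvation(self, idx: np.ndarray) -> float:
        if not self.use_solvation:
            return 0.0
        p = self.params
        h = np.maximum(p.hydropathy[idx], 0.0)
        short = np.maximum(p.n_contact_threshold - self.contacts, 0)
        return float(p.solvation_scale * np.sum(h * short) / p.n_contact_threshold)

    def total(self, idx: np.ndarray) -> float:
        return self.pair_energy(idx) + self.e_hb + self.solvation(idx)

    def mutation_delta(self, idx: np.ndarray, pos: int, new_type: int) -> float:
        """Energy change of mutating site pos to new_type (incremental)."""
        p = self.params
        old_type = idx[pos]
        row = self.switch[pos]
        de = p.pair_scale * float(
            (p.eps_matrix[new_type, idx] - p.eps_matrix[old_type, idx]) @ row)
        if self.use_solvation:
            short = max(p.n_contact_threshold - int(self.contacts[pos]), 0)
            de += (p.solvation_scale * short / p.n_contact_threshold
                   * (max(p.hydropathy[new_type], 0.0)
                      - max(p.hydropathy[old_type], 0.0)))
        return de


class _ReplicaSeq:
    """Mutable per-replica design state (internal)."""

    __slots__ = ("idx", "counts", "energy", "ln_nperm")

    def __init__(self, idx, counts, energy, ln_nperm):
        self.idx = idx
        self.counts = counts
        self.energy = energy
        self.ln_nperm = ln_nperm


def _step_inplace(state: _ReplicaSeq, target: DesignTarget, alpha_idx,
                  t_design: float, lambda_het: float, rng) -> bool:
    """One single-point-mutation Metropolis step on a replica, in place."""
    n = target.n_res
    pos = int(rng.integers(n))
    old_type = int(state.idx[pos])
    choices = alpha_idx[alpha_idx != old_type]
    if choices.size == 0:
        return False
    new_type = int(choices[rng.integers(choices.size)])
    de = target.mutation_delta(state.idx, pos, new_type)
    # d lnNperm for moving one residue from old_type to new_type
    dln = (np.log(state.counts[old_type])
           - np.log(state.counts[new_type] + 1.0))
    log_acc = -de / t_design + lambda_het * dln
    if log_acc >= 0.0 or rng.random() < np.exp(log_acc):
        state.idx[pos] = new_type
        state.counts[old_type] -= 1
        state.counts[new_type] += 1
        state.energy += de
        state.ln_nperm += dln
        return True
    return False


def mutation_step(state: SequenceSample, target, t_design: float,
                  lambda_het: float, params: ModelParameters = None,
                  rng: np.random.Generator = None,
                  alphabet: str = AA_ALPHABET) -> SequenceSample:
    """Propose and Metropolis-accept one single-point mutation.

    target may be a ChainGeometry (context built on the fly) or a prebuilt
    DesignTarget.  Returns a new SequenceSample; the input is not modified.
    """
    if t_design <= 0:
        raise ValueError("design temperature must be positive")
    if not isinstance(target, DesignTarget):
        target = DesignTarget(target, params or ModelParameters())
    rng = rng if rng is not None else np.random.default_rng()
    alpha_idx = np.array([AA_INDEX[c] for c in alphabet], dtype=np.int64)
    rep = _ReplicaSeq(state.sequence.indices, state.sequence.counts,
                      state.energy, state.ln_nperm)
    _step_inplace(rep, target, alpha_idx, t_design, lambda_het, rng)
    seq = Sequence("".join(AA_ALPHABET[i] for i in rep.idx))
    return SequenceSample(seq, rep.energy, rep.ln_nperm,
                          state.temp_index, state.sweep + 1)


def design_run(target, temps, n_sweeps: int, lambda_het: float = 1.0,
               params: ModelParameters | None = None,
               rng=None, *, alphabet: str = AA_ALPHABET,
               use_solvation: bool = False, sample_stride: int = 1,
               initial: Sequence | None = None) -> list[SequenceSample]:
    """Parallel-tempering design: per-sweep mutation passes plus neighbour swaps.

    temps is the design-temperature ladder (ascending); each sweep attempts
    n_res mutations per replica, then one alternating even/odd pass of
    neighbour swap attempts.  Samples from every replica are recorded every
    sample_stride sweeps.  Fully reproducible given an integer seed or a
    seeded Generator.
    """
    params = params or ModelParameters()
    temps = np.atleast_1d(np.asarray(temps, dtype=float))
    if temps.size < 1 or np.any(temps <= 0):
        raise ValueError("need at least one positive design temperature")
    if not isinstance(target, DesignTarget):
        target = DesignTarget(target, params, use_solvation=use_solvation)
    master = np.random.default_rng(rng)
    alpha_idx = np.array(sorted(AA_INDEX[c] for c in set(alphabet)),
                         dtype=np.int64)
    n = target.n_res
    replicas = []
    for _ in temps:
        seq = initial if initial is not None else Sequence.random(
            n, master, alphabet)
        idx = seq.indices
        counts = seq.counts
        replicas.append(_ReplicaSeq(idx, counts, target.total(idx),
                                    log_multinomial(counts)))
    samples: list[SequenceSample] = []
    for sweep in range(n_sweeps):
        for ti, rep in enumerate(replicas):
            for _ in range(n):
                _step_inplace(rep, target, alpha_idx, temps[ti],
                              lambda_het, master)
        # neighbour swaps; lambda_het cancels from the detailed-balance ratio
        for parity in (0, 1):
            for i in range(parity, temps.size - 1, 2):
                de = replicas[i].energy - replicas[i + 1].energy
                log_acc = (1.0 / temps[i] - 1.0 / temps[i + 1]) * de
                if log_acc >= 0.0 or master.random() < np.exp(log_acc):
                    replicas[i], replicas[i + 1] = replicas[i + 1], replicas[i]
        if (sweep + 1) % sample_stride == 0:
            for ti, rep in enumerate(replicas):
                seq = Sequence("".join(AA_ALPHABET[k] for k in rep.idx))
                samples.append(SequenceSample(seq, rep.energy, rep.ln_nperm,
                                              ti, sweep + 1))
    return samples


@dataclass
class LandauSurface:
    """F(E, lnN_perm) = -T ln H over the sampled 2D histogram.

    hist is the normalized histogram; free_energy is a masked array defined
    only on occupied bins.  argmin_bin is the (i, j) index of the minimum-F
    occupied bin.
    """

    e_edges: np.ndarray
    lnn_edges: np.ndarray
    hist: np.ndarray
    free_energy: np.ma.MaskedArray
    t_design: float
    argmin_bin: tuple = field(default=(0, 0))

    @property
    def f_min(self) -> float:
        return float(self.free_energy[self.argmin_bin])


def landau_surface(samples, t_design: float, bins=50) -> LandauSurface:
    """Normalized 2D histogram over (E, lnN_perm) and its Landau free energy."""
    if len(samples) == 0:
        raise ValueError("no samples to histogram")
    e = np.array([s.energy for s in samples])
    lnn = np.array([s.ln_nperm for s in samples])
    hist, e_edges, lnn_edges = np.histogram2d(e, lnn, bins=bins)
    hist = hist / hist.sum()
    occupied = hist > 0
    with np.errstate(divide="ignore"):
        f = -t_design * np.log(np.where(occupied, hist, 1.0))
    fm = np.ma.MaskedArray(f, mask=~occupied)
    argmin = np.unravel_index(np.ma.argmin(fm), fm.shape)
    return LandauSurface(e_edges, lnn_edges, hist, fm, t_design,
                         tuple(int(k) for k in argmin))


def _bin_of(surface: LandauSurface, s: SequenceSample):
    i = np.searchsorted(surface.e_edges, s.energy, side="right") - 1
    j = np.searchsorted(surface.lnn_edges, s.ln_nperm, side="right") - 1
    i = min(max(i, 0), surface.hist.shape[0] - 1)
    j = min(max(j, 0), surface.hist.shape[1] - 1)
    return i, j


def select_sequences(surface: LandauSurface, samples, k: int,
                     mode: str = "lowF") -> list[SequenceSample]:
    """Pick k distinct sequences: "lowF" from minimal-F occupied bins (ties
    broken by lower E, then first-seen order); "lowE" by raw energy minimum."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("lowF", "lowE"):
        raise ValueError("mode must be 'lowF' or 'lowE'")
    if mode == "lowE":
        order = sorted(range(len(samples)),
                       key=lambda i: (samples[i].energy, i))
    else:
        f_of = {}
        keys = []
        for i, s in enumerate(samples):
            b = _bin_of(surface, s)
            if b not in f_of:
                fb = surface.free_energy[b]
                f_of[b] = float(fb) if fb is not np.ma.masked else np.inf
            keys.append((f_of[b], samples[i].energy, i))
        order = sorted(range(len(samples)), key=lambda i: keys[i])
    picked, seen = [], set()
    for i in order:
        s = samples[i]
        if s.sequence.residues in seen:
            continue
        seen.add(s.sequence.residues)
        picked.append(s)
        if len(picked) == k:
            return picked
    raise ValueError(
        f"only {len(picked)} distinct sequences available, requested {k}")


def hydropathy_profile(seqs, window: int = 1, hydropathy=None) -> np.ndarray:
    """Per-position mean hydropathy over sequences, optionally window-smoothed.

    Returns an (n, 2) array of (1-based position, value).  Smoothing uses a
    centred window truncated at the chain ends (the average runs over the
    positions actually inside the chain).
    """
    if hydropathy is None:
        from .fixtures import load_tables

        hydropathy = load_tables()[1]
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    idx = np.stack([s.indices if isinstance(s, Sequence)
                    else Sequence(str(s)).indices for s in seqs])
    prof = hydropathy[idx].mean(axis=0)
    if window > 1:
        half = window // 2
        sm = np.empty_like(prof)
        for i in range(prof.size):
            lo, hi = max(0, i - half), min(prof.size, i + half + 1)
            sm[i] = prof[lo:hi].mean()
        prof = sm
    pos = np.arange(1, prof.size + 1)
    return np.column_stack([pos, prof])
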