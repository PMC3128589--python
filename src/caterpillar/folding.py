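"""Conformational Monte Carlo for a fixed sequence: replica exchange over
(phi, psi) torsions, DRMSD histograms and free-energy profiles F(DRMSD).

The sampler works on any torsion potential exposing energy(phi, psi); the
caterpillar potential additionally provides a compiled sweep so production
runs stay fast.  Moves are single-torsion perturbations: a small local
displacement (uniform in [-delta, +delta]) or, with probability pivot_prob,
a full-circle redraw of the torsion, which rotates the downstream tail of
the chain (a pivot).  Both proposal densities are symmetric, so plain
Metropolis acceptance min{1, exp(-dE/T)} is correct; hard-core overlaps are
rejected outright.  Neighbour replica swaps are attempted after every sweep
in an alternating even/odd pattern with the standard acceptance
min{1, exp[(1/T_i - 1/T_j)(E_i - E_j)]}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .energy import EnergyBreakdown, ModelParameters, total_energy
from .geometry import ChainGeometry, InternalCoordinates, build_backbone, drmsd

__all__ = [
    "TorsionPotential",
    "CaterpillarPotential",
    "HarmonicTorsionPotential",
    "ReplicaState",
    "FreeEnergyProfile",
    "FoldingResult",
    "default_movable",
    "propose_move",
    "metropolis_step",
    "replica_exchange_run",
    "free_energy_profile",
    "refold_assessment",
    "wham_free_energy",
]


def _wrap(x: float) -> float:
    if x > np.pi:
        return x - 2.0 * np.pi
    if x < -np.pi:
        return x + 2.0 * np.pi
    return x


def default_movable(n_res: int) -> np.ndarray:
    """All defined torsions: (residue, 0=phi | 1=psi) excluding the termini."""
    out = [(i, t) for i in range(n_res) for t in (0, 1)
           if not (i == 0 and t == 0) and not (i == n_res - 1 and t == 1)]
    return np.array(out, dtype=np.int64)


class TorsionPotential:
    """Interface for samplable torsion energies; subclasses define energy()."""

    uses_coords = False

    def energy(self, phi: np.ndarray, psi: np.ndarray) -> float:
        raise NotImplementedError

    def sweep(self, phi, psi, coords, trial, movable, rand, e_total,
              temperature, delta_local, pivot_prob):
        """Reference Metropolis sweep; the compiled path mirrors this exactly."""
        n_mov = movable.shape[0]
        accepted = 0
        for m in range(rand.shape[0]):
            k = min(int(rand[m, 0] * n_mov), n_mov - 1)
            res, tor = movable[k]
            arr = phi if tor == 0 else psi
            old = arr[res]
            if rand[m, 1] < pivot_prob:
                arr[res] = -np.pi + 2.0 * np.pi * rand[m, 2]
            else:
                arr[res] = _wrap(old + delta_local * (2.0 * rand[m, 2] - 1.0))
            e_new = self.energy(phi, psi)
            de = e_new - e_total
            if np.isfinite(e_new) and (
                    de <= 0.0 or rand[m, 3] < np.exp(-de / temperature)):
                e_total = e_new
                accepted += 1
            else:
                arr[res] = old
        return e_total, accepted


class CaterpillarPotential(TorsionPotential):
    """Full caterpillar model energy for a fixed sequence (compiled sweep)."""

    uses_coords = True

    def __init__(self, seq, params: ModelParameters | None = None,
                 use_solvation: bool = False,
                 ic: InternalCoordinates | None = None):
        from .energy import _seq_indices

        self.params = params or ModelParameters()
        self.seq_idx = _seq_indices(seq)
        self.use_solvation = use_solvation
        self.ic = ic or InternalCoordinates()
        self._ic_arr = self.ic.as_array()
        n = self.seq_idx.shape[0]
        self._scratch = np.empty((n, 5, 3))
        self._kargs = self.params._kernel_args(use_solvation)

    @property
    def n_res(self) -> int:
        return self.seq_idx.shape[0]

    def rebuild(self, phi, psi, coords=None) -> np.ndarray:
        if coords is None:
            coords = np.empty((self.n_res, 5, 3))
        _kernels.rebuild_chain(phi, psi, self._ic_arr, coords)
        return coords

    def energy(self, phi, psi) -> float:
        self.rebuild(phi, psi, self._scratch)
        ep, eh, es, ov = _kernels.chain_energy(self._scratch, self.seq_idx,
                                               *self._kargs)
        if ov > 0.5:
            return np.inf
        return float(ep + eh + es)

    def breakdown(self, phi, psi) -> EnergyBreakdown:
        self.rebuild(phi, psi, self._scratch)
        ep, eh, es, ov = _kernels.chain_energy(self._scratch, self.seq_idx,
                                               *self._kargs)
        if ov > 0.5:
            return EnergyBreakdown.overlapping()
        return EnergyBreakdown(float(ep), float(eh), float(es))

    def sweep(self, phi, psi, coords, trial, movable, rand, e_total,
              temperature, delta_local, pivot_prob):
        return _kernels.fold_sweep(phi, psi, coords, trial, self.seq_idx,
                                   movable, rand, e_total, temperature,
                                   delta_local, pivot_prob, self._ic_arr,
                                   *self._kargs)


class HarmonicTorsionPotential(TorsionPotential):
    """E = kappa/2 * (theta - theta0)^2 summed over selected torsions.

    A closed-form Gaussian reference system: at temperature T each torsion's
    stationary variance is T/kappa (wrap-around negligible for kappa >> T).
    """

    def __init__(self, terms):
        # terms: iterable of (residue, 0|1, kappa, theta0)
        self.terms = [(int(r), int(t), float(k), float(th)) for r, t, k, th in terms]

    def energy(self, phi, psi) -> float:
        e = 0.0
        for res, tor, kappa, theta0 in self.terms:
            x = (phi[res] if tor == 0 else psi[res]) - theta0
            e += 0.5 * kappa * x * x
        return e


@dataclass
class ReplicaState:
    """One replica: torsion state, its coordinates (if any) and bookkeeping."""

    phi: np.ndarray
    psi: np.ndarray
    coords: np.ndarray | None
    energy: float
    accepted: int = 0
    attempted: int = 0

    def chain(self, ic: InternalCoordinates | None = None) -> ChainGeometry:
        tors = np.column_stack([self.phi, self.psi])
        return build_backbone(tors, ic)


def _init_state(potential, start, n_res):
    if isinstance(start, ChainGeometry):
        tors = start.torsions
    elif isinstance(start, np.ndarray):
        tors = start
    elif start == "extended":
        tors = np.full((n_res, 2), np.pi)
    else:
        raise ValueError(f"unknown start {start!r}")
    phi = np.nan_to_num(np.ascontiguousarray(tors[:, 0]), nan=np.pi).copy()
    psi = np.nan_to_num(np.ascontiguousarray(tors[:, 1]), nan=np.pi).copy()
    coords = potential.rebuild(phi, psi) if potential.uses_coords else None
    e = potential.energy(phi, psi)
    if not np.isfinite(e):
        raise ValueError("initial conformation has a hard-core overlap")
    return ReplicaState(phi, psi, coords, e)


def propose_move(state: ReplicaState, kind: str, rng,
                 movable=None, delta_local: float = 0.3):
    """Propose a trial torsion vector (symmetric proposal); state untouched."""
    n = state.phi.shape[0]
    movable = movable if movable is not None else default_movable(n)
    k = int(rng.integers(movable.shape[0]))
    res, tor = movable[k]
    phi, psi = state.phi.copy(), state.psi.copy()
    arr = phi if tor == 0 else psi
    if kind == "pivot":
        arr[res] = rng.uniform(-np.pi, np.pi)
    elif kind == "local":
        arr[res] = _wrap(arr[res] + rng.uniform(-delta_local, delta_local))
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return phi, psi, (int(res), int(tor))


def metropolis_step(state: ReplicaState, potential: TorsionPotential,
                    temperature: float, rng, movable=None,
                    delta_local: float = 0.3,
                    pivot_prob: float = 0.2) -> ReplicaState:
    """Single Metropolis move, in place; overlaps auto-reject."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kind = "pivot" if rng.random() < pivot_prob else "local"
    phi, psi, _ = propose_move(state, kind, rng, movable, delta_local)
    e_new = potential.energy(phi, psi)
    de = e_new - state.energy
    state.attempted += 1
    if np.isfinite(e_new) and (de <= 0.0 or rng.random() < np.exp(-de / temperature)):
        state.phi, state.psi = phi, psi
        if potential.uses_coords:
            state.coords = potential.rebuild(phi, psi, state.coords)
        state.energy = e_new
        state.accepted += 1
    return state


@dataclass
class FoldingResult:
    """Per-temperature traces and summaries of a replica-exchange run."""

    temps: np.ndarray
    drmsd_traces: list  # per temperature: array of DRMSD values (if target)
    energy_traces: list  # per temperature: array of total energies
    acceptance: np.ndarray  # per-temperature move acceptance fraction
    swap_acceptance: float
    best_chain: ChainGeometry | None  # lowest-DRMSD recorded conformation
    best_drmsd: float
    final_states: list
    record_stride: int
    obs_traces: list = field(default_factory=list)  # optional observable

    def histogram(self, temp_index: int, bin_width: float = 0.1):
        vals = self.drmsd_traces[temp_index]
        hi = max(float(np.max(vals)) + bin_width, bin_width)
        edges = np.arange(0.0, hi + bin_width, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        return counts, edges


def _spawn_rngs(rng, n):
    if isinstance(rng, np.random.Generator):
        seeds = rng.integers(2**31, size=n)
        return [np.random.default_rng(int(s)) for s in seeds]
    ss = np.random.SeedSequence(rng)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def replica_exchange_run(seq, temps, n_sweeps: int,
                         target: ChainGeometry | None = None,
                         params: ModelParameters | None = None,
                         rng=None, *, potential: TorsionPotential | None = None,
                         movable=None, start="extended",
                         delta_local: float = 0.3, pivot_prob: float = 0.2,
                         record_stride: int = 5, use_solvation: bool = False,
                         drift_check_stride: int = 1000,
                         checkpoint_path=None, n_res: int | None = None,
                         observable=None) -> FoldingResult:
    """Replica-exchange Monte Carlo over conformations of a fixed sequence.

    By default builds a CaterpillarPotential for seq; pass potential= to
    sample a toy system instead.  If target is given, the DRMSD to it is
    recorded every record_stride sweeps at every temperature and the overall
    lowest-DRMSD conformation is kept.  Reproducible given an integer seed.
    """
    temps = np.atleast_1d(np.asarray(temps, dtype=float))
    if temps.size < 1 or np.any(temps <= 0):
        raise ValueError("need at least one positive temperature")
    if potential is None:
        potential = CaterpillarPotential(seq, params, use_solvation)
    if n_res is None:
        n_res = getattr(potential, "n_res", None) or (
            target.n_res if target is not None else len(seq))
    movable = (np.asarray(movable, dtype=np.int64) if movable is not None
               else default_movable(n_res))
    n_moves = movable.shape[0]
    # move parameters may be given per temperature rung
    deltas = np.broadcast_to(np.asarray(delta_local, dtype=float),
                             temps.shape).copy()
    pivots = np.broadcast_to(np.asarray(pivot_prob, dtype=float),
                             temps.shape).copy()
    rngs = _spawn_rngs(rng, temps.size + 1)
    swap_rng = rngs[-1]
    states = [_init_state(potential, start, n_res) for _ in temps]
    trial = (np.empty((n_res, 5, 3)) if potential.uses_coords else None)
    target_ca = (np.ascontiguousarray(target.ca) if target is not None else None)
    traces_d = [[] for _ in temps]
    traces_e = [[] for _ in temps]
    traces_o = [[] for _ in temps]
    accepted = np.zeros(temps.size)
    swap_acc = 0
    swap_att = 0
    best_d = np.inf
    best_tors = None
    chunk = 256  # sweeps of pre-drawn uniforms per replica
    rand_blocks = [None] * temps.size
    for sweep in range(n_sweeps):
        off = sweep % chunk
        for ti in range(temps.size):
            if off == 0:
                rand_blocks[ti] = rngs[ti].random((min(chunk, n_sweeps - sweep),
                                                   n_moves, 4))
            st = states[ti]
            e, acc = potential.sweep(st.phi, st.psi, st.coords, trial,
                                     movable, rand_blocks[ti][off], st.energy,
                                     temps[ti], deltas[ti], pivots[ti])
            st.energy = e
            st.accepted += acc
            st.attempted += n_moves
            accepted[ti] += acc
        parity = sweep % 2
        for i in range(parity, temps.size - 1, 2):
            de = states[i].energy - states[i + 1].energy
            log_acc = (1.0 / temps[i] - 1.0 / temps[i + 1]) * de
            swap_att += 1
            if log_acc >= 0.0 or swap_rng.random() < np.exp(log_acc):
                states[i], states[i + 1] = states[i + 1], states[i]
                swap_acc += 1
        if (sweep + 1) % record_stride == 0:
            for ti, st in enumerate(states):
                traces_e[ti].append(st.energy)
                if observable is not None:
                    traces_o[ti].append(observable(st))
                if target_ca is not None:
                    ca = (st.coords[:, 1, :] if st.coords is not None
                          else potential.rebuild(st.phi, st.psi)[:, 1, :])
                    d = float(_kernels.drmsd_kernel(
                        np.ascontiguousarray(ca), target_ca))
                    traces_d[ti].append(d)
                    if d < best_d:
                        best_d = d
                        best_tors = np.column_stack([st.phi, st.psi])
        if (sweep + 1) % drift_check_stride == 0:
            for st in states:
                e_full = potential.energy(st.phi, st.psi)
                if abs(e_full - st.energy) > 1e-6 * max(1.0, abs(e_full)):
                    raise RuntimeError(
                        f"energy bookkeeping drift: {st.energy} vs {e_full}")
                st.energy = e_full
        if checkpoint_path is not None and (sweep + 1) % max(
                n_sweeps // 4, 1) == 0:
            _save_checkpoint(checkpoint_path, states, sweep + 1, temps)
    best_chain = None
    if best_tors is not None:
        ic = getattr(potential, "ic", None)
        best_chain = build_backbone(best_tors, ic)
    return FoldingResult(
        temps=temps,
        drmsd_traces=[np.array(t) for t in traces_d],
        energy_traces=[np.array(t) for t in traces_e],
        acceptance=accepted / (n_sweeps * n_moves),
        swap_acceptance=(swap_acc / swap_att) if swap_att else float("nan"),
        best_chain=best_chain,
        best_drmsd=best_d,
        final_states=states,
        record_stride=record_stride,
        obs_traces=[np.array(t) for t in traces_o],
    )


def _save_checkpoint(path, states, sweep, temps):
    np.savez(path,
             sweep=sweep,
             temps=temps,
             phi=np.stack([s.phi for s in states]),
             psi=np.stack([s.psi for s in states]),
             energy=np.array([s.energy for s in states]))


def load_checkpoint(path):
    """Return (torsions_per_replica, energies, sweep, temps) from a checkpoint."""
    d = np.load(path)
    tors = [np.column_stack([p, q]) for p, q in zip(d["phi"], d["psi"])]
    return tors, d["energy"], int(d["sweep"]), d["temps"]


@dataclass
class FreeEnergyProfile:
    """F(DRMSD) = -T ln P on occupied bins, shifted so min F = 0."""

    edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ma.MaskedArray
    temperature: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def probability(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def free_energy_profile(histogram, temperature: float,
                        bin_width: float = 0.1) -> FreeEnergyProfile:
    """Build F(DRMSD) from a histogram (counts, edges) or raw DRMSD samples."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(histogram, tuple):
        counts, edges = histogram
        counts = np.asarray(counts, dtype=float)
        edges = np.asarray(edges, dtype=float)
    else:
        vals = np.asarray(histogram, dtype=float)
        if vals.size == 0:
            raise ValueError("empty histogram")
        hi = max(float(vals.max()) + bin_width, bin_width)
        edges = np.arange(0.0, hi + bin_width, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        counts = counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("empty histogram")
    p = counts / counts.sum()
    occ = p > 0
    with np.errstate(divide="ignore"):
        f = -temperature * np.log(np.where(occ, p, 1.0))
    f = f - f[occ].min()
    return FreeEnergyProfile(edges, counts,
                             np.ma.MaskedArray(f, mask=~occ), temperature)


@dataclass
class RefoldSummary:
    drmsd_min: float  # bin centre of the global F minimum
    barrier: float  # largest downhill barrier from the unfolded side


def refold_assessment(profile: FreeEnergyProfile) -> RefoldSummary:
    """Locate the global F minimum and the largest barrier on the way in.

    Scans from the highest occupied DRMSD bin toward the global minimum,
    tracking the running minimum of F; the barrier is the largest excess of
    F over that running minimum encountered before reaching the global
    minimum.
    """
    f = profile.free_energy
    occ = np.where(~f.mask)[0]
    centers = profile.centers
    gmin = int(occ[np.ma.argmin(f[occ])])
    barrier = 0.0
    running = np.inf
    for i in occ[::-1]:
        if i < gmin:
            break
        fi = float(f[i])
        running = min(running, fi)
        barrier = max(barrier, fi - running)
    return RefoldSummary(float(centers[gmin]), float(barrier))


def wham_free_energy(energy_traces, drmsd_traces, temps, t_out: float,
                     bin_width: float = 0.1, n_iter: int = 200,
                     tol: float = 1e-8) -> FreeEnergyProfile:
    """Multiple-histogram (WHAM) combination of replica-exchange traces.

    Optional refinement over the single-temperature estimate: reweights all
    samples from every temperature to t_out.  Traces must be index-aligned
    lists of per-temperature arrays.
    """
    temps = np.asarray(temps, dtype=float)
    e_all = np.concatenate(energy_traces)
    q_all = np.concatenate(drmsd_traces)
    n_k = np.array([len(t) for t in energy_traces], dtype=float)
    beta_k = 1.0 / temps
    f_k = np.zeros(temps.size)
    # log-sum-exp WHAM iteration for the sample normalizers
    for _ in range(n_iter):
        log_denom = _logsumexp_matrix(-np.outer(beta_k, e_all).T
                                      + (np.log(n_k) + f_k)[None, :])
        new_f = -np.array([
            _logsumexp(-beta_k[k] * e_all - log_denom) for k in range(temps.size)
        ])
        new_f -= new_f[0]
        if np.max(np.abs(new_f - f_k)) < tol:
            f_k = new_f
            break
        f_k = new_f
    log_denom = _logsumexp_matrix(-np.outer(beta_k, e_all).T
                                  + (np.log(n_k) + f_k)[None, :])
    log_w = -e_all / t_out - log_denom
    log_w -= log_w.max()
    w = np.exp(log_w)
    hi = max(float(q_all.max()) + bin_width, bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(q_all, bins=edges, weights=w)
    return free_energy_profile((counts, edges), t_out)


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


def _logsumexp_matrix(x):
    m = np.max(x, axis=1, keepdims=True)
    return (m + np.log(np.sum(np.exp(x - m), axis=1, keepdims=True))).ravel()
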