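"""Synthetic structures, toy systems, and the embedded parameter tables.

Everything other modules need for testing is generated here at run time:
ideal secondary-structure fixtures, seeded compact toy conformations, and
the small exhaustively-enumerable design system shared by the sampler
correctness tests.  The two parameter tables ship with the package as plain
text and are checksum-guarded against tampering.

The contact-energy table is a synthetic stand-in (see its file header): a
contact potential of the statistical-potential family constructed from the
Kyte-Doolittle hydropathy scale, not a reproduction of any published matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_ideal_helix",
    "make_beta_hairpin",
    "make_compact_toy",
    "make_extended",
    "load_tables",
    "toy_design_system",
    "HELIX_PHI_DEG",
    "HELIX_PSI_DEG",
]

HELIX_PHI_DEG = -57.0
HELIX_PSI_DEG = -47.0

_TABLE_SHA256 = {
    "contact_matrix_synthetic.tsv":
        "b9f0f64b5dbc10d8502449c55e1f1f1ec79db9142b88c00c6f1032e9532c9611",
    "hydropathy_kyte_doolittle.tsv":
        "b7fc26bd184beec76b75d5a03881afedb7f21ec7cc049ab3734637c5d8a8f414",
}

_tables_cache = None


def _read_table(name: str) -> bytes:
    data = resources.files("caterpillar.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE_SHA256[name]:
        raise ValueError(f"checksum mismatch for embedded table {name}")
    return data


def load_tables():
    """Return (eps_matrix 20x20, hydropathy 20-vector), checksum-verified.

    Row/column order follows the one-letter alphabetical amino-acid order of
    the table headers (identical to energy.AA_ALPHABET).
    """
    global _tables_cache
    if _tables_cache is not None:
        return _tables_cache[0].copy(), _tables_cache[1].copy()
    from .energy import AA_ALPHABET

    lines = [l for l in _read_table("contact_matrix_synthetic.tsv")
             .decode().splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    if "".join(header) != AA_ALPHABET:
        raise ValueError("contact matrix header does not match the alphabet")
    eps = np.zeros((20, 20))
    for i, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if parts[0] != AA_ALPHABET[i]:
            raise ValueError("contact matrix row order does not match the alphabet")
        eps[i] = [float(x) for x in parts[1:]]
    if not np.array_equal(eps, eps.T):
        raise ValueError("contact matrix is not symmetric")

    hlines = [l for l in _read_table("hydropathy_kyte_doolittle.tsv")
              .decode().splitlines() if l and not l.startswith("#")][1:]
    hyd = np.zeros(20)
    for line in hlines:
        aa, val = line.split("\t")
        hyd[AA_ALPHABET.index(aa)] = float(val)
    _tables_cache = (eps, hyd)
    return eps.copy(), hyd.copy()


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for a synthetic structure; same spec => same fixture."""

    kind: str  # ideal_helix | beta_hairpin | compact_toy | extended
    length: int
    seed: int = 0


def make_fixture(spec: FixtureSpec, params=None):
    if spec.kind == "ideal_helix":
        return make_ideal_helix(spec.length)
    if spec.kind == "beta_hairpin":
        return make_beta_hairpin(spec.length)
    if spec.kind == "compact_toy":
        return make_compact_toy(spec.length, spec.seed, params)
    if spec.kind == "extended":
        return make_extended(spec.length)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_extended(n: int):
    """Fully extended chain: phi = psi = 180 deg everywhere."""
    from .geometry import build_backbone

    t = np.full((n, 2), np.pi)
    return build_backbone(t)


def make_ideal_helix(n: int):
    """Ideal alpha-helix, phi = -57 deg, psi = -47 deg throughout."""
    if n < 4:
        raise ValueError("helix fixture needs n >= 4")
    from .geometry import build_backbone

    t = np.tile(np.deg2rad([HELIX_PHI_DEG, HELIX_PSI_DEG]), (n, 1))
    return build_backbone(t)


# Turn torsions for the two turn residues of the hairpin (degrees), chosen so
# the strands come back antiparallel and into register while every
# non-consecutive CA pair clears the hard core with margin.
_TURN_TORSIONS_DEG = ((150.0, 0.0), (150.0, -30.0))


def make_beta_hairpin(n: int):
    """Two extended strands joined by a 2-residue turn."""
    if n < 6:
        raise ValueError("hairpin fixture needs n >= 6")
    from .geometry import build_backbone

    strand = (-120.0, 130.0)
    half = (n - 2) // 2
    tors = [strand] * half + list(_TURN_TORSIONS_DEG) + [strand] * (n - 2 - half)
    return build_backbone(np.deg2rad(tors))


def make_compact_toy(n: int, seed: int = 0, params=None, max_attempts: int = 20):
    """Seeded overlap-free compact conformation with mean contact count >= 2.

    Runs a short collapse from the extended chain under a uniform attractive
    pair term (every residue pair equally sticky) so the result is
    sequence-independent; deterministic per (n, seed).
    """
    if n < 8:
        raise ValueError("compact toy needs n >= 8")
    from .energy import ModelParameters
    from .geometry import build_backbone, contact_counts
    from . import _kernels

    if params is None:
        params = ModelParameters()
    # collapse potential: uniform attraction with a short range so the drive
    # toward compactness persists below the model's long interaction cutoff
    uniform = ModelParameters(
        eps_matrix=np.full((20, 20), -1.0),
        pair_scale=1.0,
        r_cut=8.0,
        switch_width=1.0,
        sphere_radius=params.sphere_radius,
        hb_epsilon=0.0,
    )
    # contact radius for the acceptance check: tight enough that "compact"
    # means genuinely collapsed, not merely within the long interaction range
    r_contact = 8.0
    rng = np.random.default_rng(np.random.SeedSequence([1203, seed, n]))
    for _ in range(max_attempts):
        chain = make_extended(n)
        phi = np.nan_to_num(chain.torsions[:, 0], nan=0.0).copy()
        psi = np.nan_to_num(chain.torsions[:, 1], nan=0.0).copy()
        coords = chain.coords.copy()
        trial = np.empty_like(coords)
        movable = np.array([(i, t) for i in range(n) for t in (0, 1)
                            if not (i == 0 and t == 0)
                            and not (i == n - 1 and t == 1)], dtype=np.int64)
        e = 0.0
        ep, eh, es, ov = _kernels.chain_energy(
            coords, np.zeros(n, np.int64), *uniform._kernel_args(False))
        e = ep + eh + es
        ic = chain.internal.as_array()
        for sweep in range(120):
            rand = rng.random((len(movable), 4))
            e, _ = _kernels.fold_sweep(
                phi, psi, coords, trial, np.zeros(n, np.int64), movable, rand,
                e, 0.6, 0.5, 0.3, ic, *uniform._kernel_args(False))
        tors = np.column_stack([phi, psi])
        result = build_backbone(tors)
        counts = contact_counts(result, r_contact)
        if counts.mean() >= 2.0:
            return result
    raise RuntimeError(f"collapse failed to reach a compact state for n={n}")


def toy_design_system():
    """The exhaustively enumerable design toy: a fixed compact 6-mer backbone
    and a 3-letter alphabet.

    With helical torsions every |i-j| >= 2 CA pair of the 6-mer sits inside
    the interaction range, so the pair energy genuinely discriminates among
    all 3^6 = 729 sequences.  The letters span the hydropathy range
    (I hydrophobic, A weakly so, E hydrophilic).
    """
    from .geometry import build_backbone

    t = np.tile(np.deg2rad([HELIX_PHI_DEG, HELIX_PSI_DEG]), (6, 1))
    return build_backbone(t), "AEI"
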