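"""File I/O, run configuration and the end-to-end design -> refold pipeline.

Formats: PDB for structures (read through biotite, model 1, single chain,
first altloc; written with standard ATOM records), FASTA for sequences, TSV
for tables and profiles, YAML for configuration.  Every file this module
writes starts with a comment header echoing the full run configuration and
seed, so any output can be traced back to the run that produced it.
Residue indices are 1-based in every file and 0-based everywhere in memory.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import __version__
from ._kernels import drmsd_kernel
from .design import (DesignTarget, Sequence, design_run, landau_surface,
                     select_sequences)
from .energy import AA_ALPHABET, ModelParameters, calibrate_hb_balance, total_energy
from .fixtures import FixtureSpec, make_fixture
from .geometry import (ChainGeometry, InternalCoordinates, build_backbone,
                       dihedral, rmsd_kabsch)
from .folding import free_energy_profile, refold_assessment, replica_exchange_run

__all__ = [
    "THREE_TO_ONE", "ONE_TO_THREE", "RunConfig", "read_structure",
    "write_structure", "write_fasta", "read_fasta", "write_table",
    "read_table", "pipeline_run", "PipelineReport",
]

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


# ---------------------------------------------------------------- structures

def read_structure(path, chain_id: str | None = None):
    """Read a PDB backbone and rebuild it as an idealized caterpillar chain.

    Uses model 1 only, a single chain (the flag, or the only chain present),
    first altloc, HETATM ignored; a missing backbone atom is a hard error
    naming the residue.  Returns (chain, sequence, fidelity_drmsd) where
    fidelity_drmsd measures how well the fixed-internal-coordinate rebuild
    reproduces the raw CA-CA distance matrix.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    arr = pdb.get_structure(model=1, altloc="first")
    arr = arr[~arr.hetero]
    chains = sorted(set(arr.chain_id))
    if chain_id is None:
        if len(chains) > 1:
            raise ValueError(
                f"multiple chains {chains} present; select one explicitly")
        chain_id = chains[0]
    elif chain_id not in chains:
        raise ValueError(f"chain {chain_id!r} not found (available: {chains})")
    arr = arr[arr.chain_id == chain_id]
    res_ids = []
    for rid in arr.res_id:
        if rid not in res_ids:
            res_ids.append(rid)
    raw = np.zeros((len(res_ids), 3, 3))  # N, CA, C per residue
    letters = []
    for i, rid in enumerate(res_ids):
        res = arr[arr.res_id == rid]
        name = res.res_name[0]
        if name not in THREE_TO_ONE:
            raise ValueError(f"nonstandard residue {name} at position {rid}")
        letters.append(THREE_TO_ONE[name])
        for k, atom in enumerate(("N", "CA", "C")):
            sel = res[res.atom_name == atom]
            if sel.array_length() == 0:
                raise ValueError(f"missing backbone atom {atom} in residue "
                                 f"{name} {rid} of chain {chain_id}")
            raw[i, k] = sel.coord[0]
    n = len(res_ids)
    if n < 2:
        raise ValueError("need at least two residues")
    tors = np.full((n, 2), np.nan)
    for i in range(n):
        if i > 0:
            tors[i, 0] = dihedral(raw[i - 1, 2], raw[i, 0], raw[i, 1], raw[i, 2])
        if i < n - 1:
            tors[i, 1] = dihedral(raw[i, 0], raw[i, 1], raw[i, 2], raw[i + 1, 0])
    chain = build_backbone(tors)
    fidelity = float(drmsd_kernel(np.ascontiguousarray(chain.ca),
                                  np.ascontiguousarray(raw[:, 1])))
    return chain, Sequence("".join(letters)), fidelity


def write_structure(path, chain: ChainGeometry, seq=None, header: dict | None = None):
    """Write the caterpillar backbone (N, CA, C, O and amide H) as PDB."""
    n = chain.n_res
    letters = str(seq) if seq is not None else "A" * n
    if len(letters) != n:
        raise ValueError("sequence/chain length mismatch")
    atoms = []
    for i in range(n):
        names = ["N", "CA", "C", "O"] + (["H"] if i > 0 else [])
        for k, name in enumerate(names):
            a = bst.Atom(chain.coords[i, k if name != "H" else 4],
                         atom_name=name, res_id=i + 1,
                         res_name=ONE_TO_THREE[letters[i]],
                         chain_id="A", element=name[0])
            atoms.append(a)
    arr = bst.array(atoms)
    pdb = PDBFile()
    pdb.set_structure(arr)
    lines = _header_lines(header, prefix="REMARK 200 ") + pdb.lines
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- tables

def _header_lines(header: dict | None, prefix: str = "# ") -> list[str]:
    echo = {"generator": f"caterpillar {__version__}"}
    if header:
        echo.update(header)
    return [f"{prefix}{k} = {v}" for k, v in echo.items()]


def write_fasta(path, records, header: dict | None = None):
    """Write (id, sequence) records; ';' comment lines carry the config echo."""
    with open(path, "w") as f:
        for line in _header_lines(header, prefix="; "):
            f.write(line + "\n")
        for rid, seq in records:
            f.write(f">{rid}\n")
            s = str(seq)
            for i in range(0, len(s), 60):
                f.write(s[i:i + 60] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from biotite.sequence.io.fasta import FastaFile

    text = "\n".join(l for l in Path(path).read_text().splitlines()
                     if not l.startswith(";"))
    ff = FastaFile.read(_io.StringIO(text))
    return [(rid, str(seq)) for rid, seq in ff.items()]


def write_table(path, df: pd.DataFrame, header: dict | None = None):
    with open(path, "w") as f:
        for line in _header_lines(header):
            f.write(line + "\n")
        df.to_csv(f, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_file_header(path) -> dict:
    """Parse the 'key = value' comment echo at the top of any output file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith(("#", ";", "REMARK 200 ")):
            body = line.removeprefix("REMARK 200 ").lstrip("#; ").strip()
            if " = " in body:
                k, v = body.split(" = ", 1)
                out[k.strip()] = v.strip()
        elif line.strip():
            break
    return out


# ------------------------------------------------------------ configuration

@dataclass
class RunConfig:
    """Fully serializable description of a design -> refold pipeline run."""

    # target: a PDB path or a fixture spec (kind/length)
    target_pdb: str | None = None
    target_chain: str | None = None
    fixture_kind: str | None = "ideal_helix"
    fixture_length: int = 16
    # design stage
    design_temps: list = field(default_factory=lambda: list(
        np.geomspace(0.05, 2.0, 8).round(6)))
    design_sweeps: int = 1000
    lambda_het: float = 1.0
    design_analysis_temp: float = 0.25
    n_select: int = 3
    landau_bins: int = 50
    # folding stage
    fold_temps: list = field(default_factory=lambda: [0.25, 0.4, 0.6, 0.9])
    fold_sweeps: int = 200_000
    record_stride: int = 5
    delta_local: float = 0.3
    pivot_prob: float = 0.2
    bin_width: float = 0.1
    start: str = "extended"
    # model
    use_solvation: bool = False
    calibrate_pair_scale: bool = False  # defaults are refolding-calibrated
    param_overrides: dict = field(default_factory=dict)
    # bookkeeping
    seed: int = 0
    out_dir: str = "caterpillar_run"

    def params(self) -> ModelParameters:
        return ModelParameters(**self.param_overrides)

    def echo(self) -> dict:
        d = asdict(self)
        d["design_temps"] = list(map(float, d["design_temps"]))
        return {k: v for k, v in d.items()}

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.echo(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ----------------------------------------------------------------- pipeline

@dataclass
class PipelineReport:
    config: RunConfig
    pair_scale: float
    summary: pd.DataFrame
    files: list


def _load_target(config: RunConfig):
    if config.target_pdb:
        chain, seq, fidelity = read_structure(config.target_pdb,
                                              config.target_chain)
        return chain, seq, fidelity
    spec = FixtureSpec(config.fixture_kind, config.fixture_length,
                       seed=config.seed)
    chain = make_fixture(spec)
    return chain, None, 0.0


def pipeline_run(config: RunConfig) -> PipelineReport:
    """design -> Landau surface -> selection -> refold -> F(DRMSD) -> summary.

    Emits, under config.out_dir: the designed sequences (FASTA), the design
    sample table and Landau surface (TSV), per-sequence DRMSD histograms and
    free-energy profiles (TSV), best-DRMSD snapshots (PDB), the echoed
    config (YAML) and a one-row-per-sequence summary table (TSV).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = {"seed": config.seed, **{f"cfg.{k}": v for k, v in
                                    config.echo().items()}}
    files = []

    def _emit(name, writer, *args):
        path = out / name
        writer(path, *args)
        files.append(path)
        return path

    try:
        target, nat_seq, fidelity = _load_target(config)
    except Exception as exc:
        raise RuntimeError(f"[stage target] {exc}") from exc

    params = config.params()
    if config.calibrate_pair_scale:
        ref_seq = (nat_seq if nat_seq is not None else
                   Sequence.random(target.n_res,
                                   np.random.default_rng(config.seed)))
        try:
            k = calibrate_hb_balance(target, ref_seq, params)
        except Exception as exc:
            raise RuntimeError(f"[stage calibrate] {exc}") from exc
        params = params.with_pair_scale(k)
    echo["pair_scale"] = params.pair_scale

    try:
        dtarget = DesignTarget(target, params,
                               use_solvation=config.use_solvation)
        samples = design_run(dtarget, config.design_temps,
                             config.design_sweeps, config.lambda_het,
                             params, rng=config.seed,
                             use_solvation=config.use_solvation)
        temps_d = np.asarray(config.design_temps, dtype=float)
        ana = int(np.argmin(np.abs(temps_d - config.design_analysis_temp)))
        low = [s for s in samples if s.temp_index == ana
               and s.sweep > config.design_sweeps // 5]
        surface = landau_surface(low, float(temps_d[ana]),
                                 bins=config.landau_bins)
        picked = select_sequences(surface, low, config.n_select, mode="lowF")
    except Exception as exc:
        raise RuntimeError(f"[stage design] {exc}") from exc

    _emit("design_samples.tsv", write_table, pd.DataFrame(
        [{"sequence": str(s.sequence), "E": s.energy,
          "lnNperm": s.ln_nperm, "T_index": s.temp_index,
          "sweep": s.sweep} for s in samples]), echo)
    fdf = pd.DataFrame(surface.free_energy.filled(np.nan))
    _emit("landau_surface.tsv", write_table, fdf, echo)
    _emit("landau_bins.tsv", write_table, pd.DataFrame({
        "e_edge": pd.Series(surface.e_edges),
        "lnn_edge": pd.Series(surface.lnn_edges)}), echo)
    _emit("designed.fasta", write_fasta,
          [(f"design/seed{config.seed}/rank{i}_E{s.energy:.3f}", s.sequence)
           for i, s in enumerate(picked)], echo)
    config.to_yaml(out / "config.yaml")
    files.append(out / "config.yaml")

    rows = []
    t_fold_low = float(min(config.fold_temps))
    for i, s in enumerate(picked):
        try:
            res = replica_exchange_run(
                s.sequence, config.fold_temps, config.fold_sweeps,
                target=target, params=params,
                rng=np.random.SeedSequence([config.seed, 77, i])
                    .generate_state(1)[0] % (2**31),
                start=config.start, delta_local=config.delta_local,
                pivot_prob=config.pivot_prob,
                record_stride=config.record_stride,
                use_solvation=config.use_solvation)
            ti = int(np.argmin(config.fold_temps))
            counts, edges = res.histogram(ti, config.bin_width)
            prof = free_energy_profile((counts, edges), t_fold_low)
            assess = refold_assessment(prof)
        except Exception as exc:
            raise RuntimeError(f"[stage fold:{i}] {exc}") from exc
        _emit(f"hist_seq{i}.tsv", write_table, pd.DataFrame(
            {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}), echo)
        _emit(f"profile_seq{i}.tsv", write_table, pd.DataFrame(
            {"drmsd": prof.centers,
             "F": prof.free_energy.filled(np.nan)}), echo)
        if res.best_chain is not None:
            _emit(f"best_seq{i}.pdb", write_structure, res.best_chain,
                  s.sequence, echo)
        rows.append({
            "sequence": str(s.sequence),
            "E_design": s.energy,
            "lnNperm": s.ln_nperm,
            "argminF_drmsd": assess.drmsd_min,
            "barrier": assess.barrier,
            "best_drmsd": res.best_drmsd,
            "best_rmsd": (rmsd_kabsch(res.best_chain, target)
                          if res.best_chain is not None else np.nan),
        })
    summary = pd.DataFrame(rows)
    _emit("summary.tsv", write_table, summary, echo)
    return PipelineReport(config, params.pair_scale, summary, files)
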