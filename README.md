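# caterpillar

Coarse-grained protein design and folding validation by Monte Carlo.

## The problem

Designing an amino-acid sequence that folds into a chosen backbone is the
inverse of the folding problem, and it fails badly on unconstrained
off-lattice chains: energy minimization in sequence space happily produces
low-energy homopolymers that fold into anything *but* the target.  Two
ingredients rescue it — a backbone with realistic thickness and explicit,
directional hydrogen bonds, which together confine the chain to
protein-like conformations.

This package implements such a model and the complete two-stage workflow
around it, for people who study coarse-grained protein design, folding
free-energy landscapes, or Monte Carlo methodology:

1. **The model.**  One interaction sphere per residue centred on CA (a
   hard core plus a switched contact well with depths ε(a, b) from a 20×20
   contact matrix), explicit backbone N–H and C=O groups interacting
   through an angular-modulated 10–12 hydrogen-bond potential, and an
   optional hydropathy-weighted solvation penalty.  Degrees of freedom are
   the (φ, ψ) torsions only:

       E = k Σ_{|i−j|≥2} ε(a_i,a_j) S(r_ij)  +  E_hb  +  E_solv
       S(r) = ½[1 − tanh((r − r_cut)/w)]
       E_hb = Σ ε_hb[5(σ/r)¹² − 6(σ/r)¹⁰] cos^m(α−π) cos^m(β−π)

2. **Design**: parallel-tempering Metropolis in *sequence* space on a fixed
   target backbone, with acceptance
   min{1, exp(−ΔE/T + λ Δln N_perm)} — the multinomial term ln N_perm
   rewards compositional heterogeneity.  Designs are selected at the
   minimum of the Landau surface F(E, ln N_perm) = −T ln H ("LowF"), with a
   raw-energy-minimum control ("LowE").

3. **Folding validation**: replica-exchange Metropolis in *conformation*
   space for a fixed sequence, from the extended chain, yielding
   free-energy profiles F(DRMSD) = −T ln P over the distance-RMSD to the
   target.  A design succeeds when the global F minimum sits at small
   DRMSD.

The shipped contact matrix is a synthetic stand-in of the statistical
contact-potential family, built from the Kyte–Doolittle hydropathy scale
(see `docs/methods.md`).

## Worked example

Design sequences for a 16-residue ideal α-helix and refold the top pick:

```python
import numpy as np
from caterpillar import (design_run, landau_surface, select_sequences,
                         replica_exchange_run, free_energy_profile,
                         refold_assessment)
from caterpillar.fixtures import make_ideal_helix
from caterpillar.io import RunConfig

cfg = RunConfig()                       # study defaults
target = make_ideal_helix(16)
params = cfg.params()

samples = design_run(target, cfg.design_temps, cfg.design_sweeps,
                     cfg.lambda_het, params, rng=5)
temps = np.asarray(cfg.design_temps)
ana = int(np.argmin(np.abs(temps - cfg.design_analysis_temp)))
low = [s for s in samples if s.temp_index == ana and s.sweep > 200]
surface = landau_surface(low, float(temps[ana]))
best = select_sequences(surface, low, 1)[0]
print(best.sequence, round(best.energy, 2), round(best.ln_nperm, 1))

res = replica_exchange_run(best.sequence, cfg.fold_temps, cfg.fold_sweeps,
                           target=target, params=params, rng=7)
prof = free_energy_profile(res.histogram(0), min(cfg.fold_temps))
print(refold_assessment(prof))
```

Output (seeds 5 / 7):

```
WTSCESITQGAFMKYC -21.14 28.6
RefoldSummary(drmsd_min=0.15000000000000002, barrier=0.4023594781085249)
```

The designed sequence is strongly heterogeneous (ln N_perm ≈ 28.6 of a
maximum ≈ 44); refolding from the fully extended chain places the global
free-energy minimum at DRMSD ≈ 0.15 Å from the target with a small inward
barrier — the chain finds the helix.  The LowE control (`mode="lowE"`), an
almost pure Ile/Leu/Val chain with much stronger unspecific attraction,
instead tends to collapse into compact disordered states.

The same workflow is scriptable from the shell:

```bash
caterpillar fixtures --kind ideal_helix --n 16 --out helix.pdb
caterpillar design --target helix.pdb --seed 5 --out design_out
caterpillar fold --seq design_out/designed.fasta --target helix.pdb \
    --seed 7 --out fold_out
caterpillar pipeline --seed 5 --out run_out     # everything end to end
```

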