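# ifnpkpd

Semi-mechanistic PK/PD modelling of interferon-α fusion proteins
expressed *in situ* in the mouse liver after hydrodynamic plasmid
injection.

Fusing apolipoprotein A-I to interferon-α (IFNα) changes where the
cytokine goes: serum exposure rises, brain exposure and the attendant
interferon-stimulated-gene (ISG) induction change, and hepatic synthesis
slows.  Because the protein is synthesized *in vivo* from a delivered
plasmid rather than injected, classic PK analysis does not apply; the
whole cascade — plasmid → mRNA → delayed hepatic protein → serum →
brain → ISG response — has to be modelled.  This package implements that
cascade as a compartmental ODE system and everything needed to use it
quantitatively, for modellers who want to fit such data or to study the
design's identifiability with synthetic experiments:

* **model core** — the linear kinetic system (two-state plasmid
  transcription, an `n`-stage transit chain delaying hepatic synthesis,
  liver↔serum exchange, optional peripheral compartment, first-order
  brain uptake) plus saturable/linear ISG turnover models; solved either
  by a stiff-capable adaptive integrator or by exact matrix-exponential
  propagation;
* **estimation** — extended-least-squares maximum likelihood on
  log-transformed data under a proportional error model
  (Y_obs = Y_pred·(1+ε), Var ε = ω²), with the four-stage sequential
  fitting procedure (transcription → protein → brain → ISG), profiled
  per-response ω², asymptotic standard errors and CV%;
* **model selection** — likelihood-ratio tests on MVOF drops
  (χ² thresholds 3.84/6.63/10.83 at 5%/1%/0.1% for 1 df), AIC
  = N·ln(RSS/N) + 2·Np for non-nested candidates, and a precision gate
  demoting winners with CV% > 100;
* **derived quantities** — mean transit time (n+1)/k_TRAN, first-order
  half-lives, trapezoidal AUC;
* **synthetic studies** — a generator emulating the destructive mouse
  sampling design (liver/serum/brain at 6, 9, 13, 24, 48 h with 6–8
  animals per point, early serum at 1, 3, 7 h with 3), log-normal
  proportional noise, and seeded parameter-recovery experiments.

The reference parameter estimates for both molecules (the plain IFNα–GFP
fusion and the ApoAI fusion) ship in `ifnpkpd.reference` and drive all
simulations and recovery studies.  See `docs/methods.md` for the model,
its assumptions, and known identifiability limits of the emulated design.

## Worked example

```python
import numpy as np
import ifnpkpd as ip
from ifnpkpd import reference

params = reference.reference_parameters()          # both molecules
grid = np.linspace(0, 48, 961)                     # hours
for mol, p in params.items():
    traj = ip.propagate(p, grid)                   # exact linear solution
    print(mol,
          "serum peak %.3g pg/mL at %.1f h;" % (traj["serum"].max(),
                                                grid[traj["serum"].argmax()]),
          "AUC(0-48) %.3g pg*h/mL;" % ip.auc(traj, "serum", 0, 48),
          "MTT %.3g h" % ip.mean_transit_time(p.protein.k_tran,
                                              p.protein.n_transit))

ds = ip.generate_study(params, ip.StudyDesign(omega=0.2), seed=42)
print("synthetic study:", len(ds), "observations,", len(ds.responses), "responses")
```

prints

```
IFNGFP serum peak 1.53e+05 pg/mL at 5.7 h; AUC(0-48) 2.85e+06 pg*h/mL; MTT 2.76 h
IFNGFPApo serum peak 7.63e+05 pg/mL at 9.7 h; AUC(0-48) 1.39e+07 pg*h/mL; MTT 15 h
synthetic study: 290 observations, 4 responses
```

Read: the ApoAI fusion reaches a ~5-fold higher serum peak ~4 h later,
accumulates ~5-fold more serum exposure over the study (it distributes
into a peripheral pool instead of being degraded in the liver), and its
hepatic synthesis delay is 15 h versus 2.76 h for the plain fusion —
the transit chain traverses at k_TRAN = 0.266 vs 1.45 h⁻¹.  The
synthetic study emulates one full animal experiment at 20% proportional
noise, ready for `ifnpkpd.sequential_fit` or a
`ifnpkpd.recovery_experiment`.

A command-line interface covers the same pipeline:

```bash
ifnpkpd simulate --params ifngfp.yaml --out out/       # trajectory + derived
ifnpkpd generate --seed 1 --out obs.csv                # synthetic study CSV
ifnpkpd fit --data obs.csv --config fit.yaml --out fits/
ifnpkpd select fits/fit_*.json                         # LRT/AIC comparison
ifnpkpd recover --replicates 20 --seed 1 --out recovery.csv
```

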