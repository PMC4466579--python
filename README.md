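# vegftraffic

A mechanistic simulator of how endothelial cells convert the *mode of VEGF
presentation* — soluble versus matrix-immobilized — into different patterns
of site-specific VEGFR2 phosphorylation, purely through receptor
trafficking.

Vascular endothelial growth factor (VEGF-A165, modeled as a pre-dimerized
ligand V) binds its receptor tyrosine kinase VEGFR2 (R2) and the
co-receptor Neuropilin-1 (N1); matrix/heparin sites (M) immobilize VEGF
and compete with NRP1 for its heparin-binding domain. Ligated receptor is
internalized into Rab4/5 early endosomes, recycled directly or via Rab11
recycling endosomes, or degraded. Each VEGFR2 complex carries a 3-bit
phosphorylation state for Y951 (Akt/survival), Y1175 (PLCγ–ERK,
proliferation) and Y1214 (p38, migration), with first-order
phosphorylation/dephosphorylation whose rates depend on ligation state and
subcellular location — the model's encoding of compartment-localized
phosphatases. Because dephosphorylation is fast in Rab11 and slow for
Y1175 in Rab4/5, *where* a receptor is determines *which* tyrosine is
phosphorylated.

The package is aimed at systems-biology modelers of receptor tyrosine
kinase signaling and at tissue engineers who want to predict how VEGF
immobilization chemistry (k_off from the matrix) shifts the
pY1214/pY1175 balance.

## The model

Species are complexes of {V, M, R2, N1} in five compartments
(extracellular, surface, Rab4/5, Rab11, degraded); with all 8
phospho-states of every VEGFR2 form this yields 97 species, 15 reversible
binding reaction types, and 120 reversible phosphorylation reactions —
enumerated programmatically from composition rules, never hand-listed.
Dynamics are deterministic mass action, e.g. for surface V·R2:

```
d[V·R2]/dt = kon[V][R2] − koff[V·R2] − kon,M[M][V·R2] + koff,M[M·V·R2]
           − kc[N1][V·R2] + koff,N[V·N1·R2]
           − kint[V·R2] + krec4[V·R2]_rab45 + krec11[V·R2]_rab11
```

Receptor production rates are computed analytically so the no-VEGF surface
pools are stationary; simulations start from that steady state with the
stimulus installed at t = 0 (immobilized VEGF starts fully matrix-bound).
The stiff system (dephosphorylation at 30–75 s⁻¹ against trafficking at
~10⁻⁵ s⁻¹) is integrated with an implicit BDF scheme and an analytic
sparse Jacobian; an explicit adaptive 5th-order Runge–Kutta option is kept
and cross-checked to 0.1%.

Beyond simulation, the package ships the full analysis machinery:
normalized observables (pR2/pY1175/pY1214 as % of baseline VEGFR2, AUCs,
peaks, ratios), scenario and perturbation constructors (NRP1 knockout,
VEGF165b, phosphatase perturbations, k_off,V·M sweeps), bounded
multistart least-squares estimation of the six free trafficking rates with
published tie constraints, validated by synthetic-data parameter recovery,
and local ±2-fold sensitivity analysis.

## Worked example

```python
import vegftraffic as vt

net = vt.build_network()                      # 97 species, 557 reactions
for mode in ("soluble", "immobilized"):
    proto = vt.make_scenario("other", mode=mode, vegf_ng_ml=20.0,
                             duration_s=1800.0)
    tc = vt.simulate(proto, net)
    pk1175 = vt.peak(vt.phospho_series(tc, "Y1175"), (0, 1800))
    pk1214 = vt.peak(vt.phospho_series(tc, "Y1214"), (0, 1800))
    print(mode, pk1175, pk1214)
```

prints (values in % of the pre-stimulus total VEGFR2):

```
soluble      peak pY1175 = 21.4% at 12.4 min | peak pY1214 = 10.5% at 11.8 min
immobilized  peak pY1175 = 20.0% at 17.0 min | peak pY1214 = 16.6% at  8.5 min
```

Immobilizing the same 20 ng/mL dose retains ligated receptor at the cell
surface (where Y1214 dephosphorylation is slow relative to Y1175),
shifting phosphorylation toward the migration-associated Y1214 and away
from the endosomal Y1175 signal — the central prediction of the model.
The same protocols are available from the shell:

```bash
vegftraffic simulate --study other --mode immobilized --vegf-ng-ml 20 \
    --duration-min 30 --out tc.csv
vegftraffic observables --study other --mode immobilized --out summary.json
vegftraffic fit --starts 5 --seed 7 --out ensemble.json   # synthetic-data fit
vegftraffic figure fig5 --outdir out/fig5
```

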