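# gabarod

Equilibrium analysis of GABA_A receptor gating and neurosteroid modulation.

Macroscopic currents from α1β3 GABA_A receptors sag from a peak to a
steady-state plateau during sustained agonist application because receptors
accumulate in a desensitized, non-conducting but high-agonist-affinity state.
`gabarod` turns peak and steady-state open probabilities into state
occupancies in the three-state Resting–Open–Desensitized (ROD) framework,
and connects those occupancies to orthosteric radioligand binding: a ligand
that stabilizes the desensitized state can barely dent the current yet double
[³H]muscimol binding at low tracer concentrations, simply by moving resting
receptors into high-affinity states. The package is aimed at ion-channel
biophysicists and receptor pharmacologists working with two-electrode
voltage-clamp and filtration binding assays.

## The model

With agonist concentration x, the ROD equilibrium is governed by the
constitutive gating constant L (resting/open), the agonist dissociation
constants of the resting and open states K_C and K_O (K_C > K_O), the number
of binding sites N, and the open/desensitized constant Q (P_open/P_des at
steady state):

    Γ(x)            = ((1 + x/K_C) / (1 + x/K_O))^N
    P_open,peak     = 1 / (1 + LΓ)
    P_open,steady   = 1 / (1 + 1/Q + LΓ)
    P_desensitized  = 1 / (1 + Q + Q·LΓ)

In practice LΓ is read off the measured peak (LΓ = 1/P_peak − 1) and Q off
the measured steady state with LΓ fixed. A modulator that deepens the sag is
summarized by a modified Q*, transferable to other agonist concentrations
because open and desensitized states bind agonist with (approximately) equal
affinity. The predicted fold-change of low-concentration radioligand binding
is the ratio of high-affinity occupancies (P_open + P_des).

Around this core the package provides trace metrics (peak, steady state,
normalization to a maximal reference response, percent desensitization,
potentiation ratios), the standard binding-assay fits (single-site isotherm,
Hill modulation curve anchored at 100% of control, mono-exponential time
course), photolabeling-efficiency quantification, and a seeded synthetic-data
generator built on a three-site, state-dependent model of neurosteroid
action.

## Worked example

The benchmark measurements: 1 mM GABA gives peak P_open = 0.71 and
steady-state P_open = 0.121, reduced to 0.077 by 3 µM of the inhibitory
steroid epi-allopregnanolone.

```sh
gabarod occupancy 0.71 0.121 0.077
```

prints (abridged):

```json
{
  "l_gamma": 0.40845070422535223,
  "q": 0.1458573853989813,
  "q_star": 0.08636650868878357,
  "high_affinity_control": 0.9505774647887324,
  "high_affinity_treated": 0.9685492957746479,
  "binding_fold_change": 1.0189062245336415,
  "display": {
    "p_desensitized_control": 0.83,
    "p_desensitized_treated": 0.89,
    "high_affinity_control": 0.95,
    "high_affinity_treated": 0.97,
    "binding_fold_change": 1.02
  }
}
```

Reading: at saturating GABA the steroid converts open receptors into
desensitized ones (P_des 0.829 → 0.892, Q 0.146 → 0.086) but the summed
high-affinity occupancy barely moves (0.95 → 0.97, a 1.02-fold predicted
binding change) because almost no receptors are left resting. Running the
same path at 20 nM muscimol (peak 0.012, steady state 0.011 → 0.009) gives a
predicted binding fold-change of 2.75 — the same desensitizing ligand
doubles-to-triples binding when most receptors start resting, reconciling
the small current inhibition with the large binding enhancement.

The same analysis is available in Python:

```python
import gabarod as g
rep = g.estimate_from_groups([0.71], [0.121], [0.077])
rep["occupancy_control"].p_desensitized   # 0.8296
rep["binding_fold_change"]                # 1.019
```

Other subcommands: `simulate` (synthetic cells, traces and assay tables),
`fit-hill`, `fit-isotherm`, `fit-timecourse`, `desens`, `potentiation`,
`label-efficiency`, `predict-binding`. All emit self-describing JSON reports.

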