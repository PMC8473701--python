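# lferkit

Linear free energy relationship (LFER) models for predicting molecular
properties of neutral organic compounds from partition coefficients.

Many physicochemical and ADME/Tox properties — skin permeability, air/tissue
partitioning, solvent/water partition coefficients — are determined by the
free energy change of moving a solute between environments. That free energy
decomposes into contributions from molecular size, hydrogen bonding and
conformational flexibility, which motivates a linear model over descriptors
proportional to each contribution:

```
Y = b1·logP_ow + b2·S_m + b3·H_M_HBD + b4·Flex + c
```

where

* **logP_ow** is an organic-solvent/water partition coefficient on the
  hexadecane (logP_16) or octanol (logP_oct) scale, supplied by the user;
* **S_m** is a molecular-size descriptor computed from the molecular formula:
  `S_m = c + 0.3h + o + n + 2s + 0.6f + 1.8cl + 2.2br + 2.6i − 0.2·N_c3 − 0.6·N_c4`,
  with lower-case letters the element counts and N_c3/N_c4 the numbers of
  sp3 carbons bonded to exactly three/four non-fluorine heavy atoms;
* **Flex** sums categorical per-bond flexibility values (0, 0.5, 1, 1.5)
  assigned by an ordered, overridable rule table keyed to rotational barriers;
* **H_M_HBD** is the overall hydrogen-bond-donor capability on a transfer
  free-energy scale, treated as user-supplied data (an approximate built-in
  fragment estimate is available for exploration).

Models are fit by ordinary least squares with intercept and validated by
leave-one-out Q² (exact hat-matrix shortcut) and external-test-set Q². Six
published models — human skin permeability (logK_p), air-to-brain
partitioning (logK_brain, three variants) and aniline/water partitioning
(logP_aln, two variants) — ship as ready-to-use presets with their
literature coefficients and statistics.

The package is aimed at medicinal and environmental chemists who have
measured or estimated partition coefficients and want interpretable,
thermodynamically grounded property predictions without descriptor-selection
machinery.

## Worked example

```python
import lferkit as lk

mol = lk.mol_from_smiles("Oc1ccccc1O", "catechol")
print("Sm =", lk.sm_from_structure(mol))
flex, trace = lk.flex_from_structure(mol)
print("Flex =", flex)

model = lk.get_preset("logKp/logPoct")   # skin permeability from logP_oct
v = lk.DescriptorVector(s_m=9.8, flex=0.0, h_m_hbd=6.0,
                        logp_basis=0.88, basis_name="logPoct")
print("logKp =", model.predict_vector(v))
s = model.stats
print(f"model stats: n={s.n} R2={s.r2} Q2_ext={s.q2_ext} SD={s.sd} F={s.f}")
```

prints

```
Sm = 9.8
Flex = 0.0
logKp = -5.326904
model stats: n=32 R2=0.953 Q2_ext=0.966 SD=0.178 F=136.7
```

Catechol (C6H6O2) has S_m = 6 + 0.3·6 + 2 = 9.8; its two O–H bonds rotate
only hydrogens and its ring bonds are rigid, so Flex = 0. With an
experimental logP_oct of 0.88 and a donor capability of 6.0 the preset skin
model predicts logK_p ≈ −5.33 (cm/s, log10 scale) — a poorly permeant,
strongly H-bonding solute. `flex_from_structure` also returns a per-bond
trace (atom pair, value, rule that fired) for auditing.

The same workflow is available from the shell:

```bash
lfer descriptors --in mols.smi --out desc.csv --trace trace.csv
lfer fit --data table.csv --property logKp \
         --descriptors logPoct,Sm,HM_HBD,Flex --out model.json
lfer predict --model model.json --data desc.csv --out pred.csv
lfer validate --data test.csv --mode external --model model.json --report report.csv
lfer presets list
lfer simulate --n 200 --coeffs logKp/logPoct --noise-sd 0.18 --seed 1 --out synth.csv
```

sklearn users can compose `DescriptorCalculator` (a transformer) and
`LFERRegressor` (a regressor with `coef_`, `intercept_`, `stats_`) in
ordinary pipelines and model-selection tools.

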