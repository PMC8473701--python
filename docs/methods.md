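# Methods

## Model

The package implements a general linear free energy relationship for
properties of neutral organic solutes that are governed by noncovalent
interactions with flexible environments:

    Y = b1·logP_ow + b2·S_m + b3·H_M_HBD + b4·Flex + c

The rationale is thermodynamic: the free energy change ΔG_Y that determines
Y is the sum of contributions from molecular size, hydrogen-bond acceptors,
hydrogen-bond donors and conformational flexibility; choosing descriptors
proportional to each contribution makes Y linear in them. The partition
coefficient logP_ow (hexadecane/water logP_16 or octanol/water logP_oct)
stands in for the acceptor contribution, which is hard to compute directly —
logP_ow is itself a property obeying the same decomposition, so substituting
it preserves linearity. Any subset of the four predictors is a valid model;
each fitted model records exactly the coefficient set it was built with and
predicts using only that set.

Assumptions worth keeping in mind: the solute is neutral (charged and
radical species are rejected at parse time, not neutralized), and the
environment is flexible — partitioning into rigid, orientation-specific
environments such as protein binding sites is outside the model's domain.

## Descriptors

### S_m (molecular size)

Computed from the molecular formula with corrections from the structure:

    S_m = c + 0.3 h + o + n + 2 s + 0.6 f + 1.8 cl + 2.2 br + 2.6 i
          − 0.2 N_c3 − 0.6 N_c4

N_c3 (N_c4) counts sp3 carbons bonded to exactly three (four) heavy atoms,
where every non-hydrogen neighbor **except fluorine** counts as heavy. We
read that exclusion literally: Cl, Br and I do count, so chloroform's carbon
is an N_c3 center. sp3 perception is rdkit's; aromatic carbons are never
sp3, and unbranched ring CH2 carbons (two heavy neighbors) contribute to
neither count. S_m is linear in all counts and strictly positive for any
non-empty formula (the worst per-carbon correction, −0.6, is smaller than
the carbon weight of 1.0). When only a formula is available the corrections
default to zero.

### Flex (conformational flexibility)

Flex is the sum of per-bond values. Bonds to hydrogen are ignored; ring
bonds and double/triple/aromatic bonds are non-rotatable and score 0 without
rule lookup. The remaining acyclic single bonds between heavy atoms are
scored by the first matching rule of an ordered table (first match wins;
every bond's winning rule is recorded in an audit trace):

| # | rule id | value | matches |
|---|---------|-------|---------|
| 1 | `symmetric_rotation` | 0 | rotation permutes only hydrogens or three identical terminal substituents (methyl, CF3, tert-butyl tops; –OH, –NH2, terminal halogens) |
| 2 | `amide_or_aryl_carbonyl` | 0 | amide C–N; aryl–carbonyl C–C (barrier well above the CH2–CH2 reference) |
| 3 | `ether_alkyl` | 1.5 | sp3 C–O bonds where the oxygen has two heavy neighbors (ether and ester-alkyl C–O; barrier well below the reference) |
| 4 | `benzylic` | 0.5 | sp3 C–aromatic C (phenyl two-fold symmetry halves the distinguishable conformations) |
| 5 | `conjugated_sp2` | 0 | single bonds between two sp2/aromatic atoms (biphenyl, dienes, ester C(=O)–O, aryl ethers on the oxygen side) |
| 6 | `default` | 1 | everything else — the reference R1CH2–CH2R2 rotor and bond classes without a stated value |

The reference bond class defines the unit: a mid-chain CH2–CH2 rotor counts
1. Design choices where the published rule set is silent: conjugated
sp2–sp2 single bonds score 0 on the raised-barrier criterion (this is an
interpretive extension covering biphenyl-type and ester/aryl-ether
resonance); amine C–N, thioether C–S and similar unmentioned single-bond
classes fall through to the default of 1. Users can prepend SMARTS-based
rules from a plain-text file (`rule_id SMARTS value` per line, applied in
file order before the default) via `load_flex_rules` or the CLI
`--flex-rules` flag.

### H_M_HBD (donor capability)

H_M_HBD is defined as the water→hexadecane transfer free energy contributed
by the electrostatic interactions of the solute's donors. Its rigorous
computation belongs to a separate method and is **not** reproduced here;
the package treats it as data. Provider (a), the primary path, looks values
up from a user-supplied column or table and raises `MissingDescriptor` for
absent compounds. Provider (b) is an approximate built-in fragment sum
(acids > phenols > alcohols > amides > amines > thiols > polyhalogenated
CH, each counted once per donor heteroatom and scaled by the number of
donor hydrogens); its values are plausible in ordering and scale but are a
synthetic stand-in, suitable for smoke tests and exploration, not for
quantitative work. The same applies to ΔG_tr_depol in the
hydrogen-bond-acceptor analysis: it enters as a user-supplied data column.

## Fitting and statistics

Fitting is ordinary least squares with intercept (statsmodels behind
`LFERRegressor`). Rows with a missing response or descriptor are excluded —
no imputation. A rank-deficient design raises `CollinearDescriptors` naming
the columns implicated (identified by pivoted QR); fits require at least
p + 2 complete rows for p descriptors.

Reported statistics follow spreadsheet multiple-regression conventions,
which the preset models' published values also follow:

* R² = 1 − SSE/SST on the training rows;
* SD = sqrt(SSE / (n − p − 1)), the residual standard error (the n − p − 1
  convention is a design choice; the alternative n-denominator definition
  is not used anywhere);
* F = [(SST − SSE)/p] / [SSE/(n − p − 1)].

The six preset models carry their published coefficients and statistics
verbatim as literature metadata; their training tables are not shipped, so
these statistics are never recomputed, and presets are flagged
`provenance="literature"`.

## Validation

* **Q²_LOO** = 1 − PRESS/SST with PRESS the sum of squared leave-one-out
  residuals, computed exactly via the hat-matrix identity
  e_i/(1 − h_ii). The literal refit-per-row computation exists only in the
  test suite as an independent oracle; both agree to ~1e-14 relative. Any
  leverage ≥ 1 (a leave-one-out subproblem losing rank) is an error naming
  the held-out row. For OLS with intercept and all leverages < 1,
  PRESS ≥ SSE, so Q²_LOO ≤ R² always.
* **Q²_ext** = 1 − Σ(y_test − ŷ)² / Σ(y_test − ȳ_train)². The denominator
  centres on the **training** mean stored in the model's metadata — the
  common external-Q² convention; the test-mean variant is deliberately not
  offered to keep reports comparable. Train/test id overlap is an error.
* **Simple-vs-LFER comparison** fits, per compound subset, the one-variable
  regression on the logP basis and the full LFER on the same rows, and
  reports paired R²/SD. Because the simple model is nested in the LFER,
  R²_LFER ≥ R²_simple on every subset; subsets with fewer than p + 2
  complete rows are skipped with a warning. Subset labels (HBA-only, HBD,
  apolar, ...) are data columns, not perceived chemistry, so published
  groupings can be reproduced exactly.
* **HBA effect analysis** calibrates logP = a·ΔG_tr_depol + d on nonpolar
  solutes (≥ 3 rows required), then reports, for each acceptor-containing
  donor-free solute, the difference between the calibrated prediction for
  its depolarized form and its experimental logP — the acceptor
  contribution to the partition coefficient.

## Synthetic data

`GeneratorSpec`/`generate_table` emulate the statistical structure the LFER
assumes: descriptor columns sampled uniformly from realistic ranges
(logP basis ∈ [−2, 6], S_m ∈ [2, 25], H_M_HBD ∈ [0, 8], Flex on the half-unit
grid in [0, 6]) and a property column equal to a known linear combination
plus N(0, σ) noise. Defaults mirror the published skin-permeability design:
the logK_p coefficient vector on (logP_oct, S_m, H_M_HBD, Flex), σ = 0.18
log units, and n = 32. One integer seed drives a single explicit
`numpy` generator — identical spec and seed give byte-identical tables, and
the noise draws are kept in the table metadata for truth-recovery tests. An
optional correlation matrix couples descriptors through a Gaussian copula,
there to exercise collinearity diagnostics (descriptors like S_m and
H_M_HBD can correlate strongly with logP_ow in real data).

What the generator does **not** emulate: chemically consistent structures
behind the descriptor values, measurement error in the logP basis itself,
heteroscedastic or correlated residuals, and the discrete clustering of
real compound series. Passing recovery tests therefore demonstrates the
correctness of the fitting/validation machinery under the model's own
assumptions, not predictive performance on real compounds — that evidence
comes from the published statistics the presets carry.

Structures are covered separately by a packaged fixture set of ~30
molecules (alkanes, aromatics, ethers, esters, amides, halogenated and
H-bonding compounds) whose S_m, Flex and (N_c3, N_c4) values were tallied
by hand and are asserted exactly.

## Numerical choices and problem sizes

Exact-agreement checks use absolute tolerances of 1e-10 against closed-form
oracles; descriptor values are asserted to 1e-12 (they are sums of short
decimal fractions). The oracle suites use 100 random tables (n ≤ 20, p ≤ 4)
for OLS and 20 tables for LOO; parameter-recovery uses 500 replicates of
the n = 200 design, which completes in seconds. Serialized models are a
versioned JSON dialect (`lfer-model/1`); unknown fields and foreign schema
versions are rejected rather than ignored, and round-trips preserve
coefficients bit-for-bit.

## Limitations

* Neutral compounds only; ionizable species must be handled upstream
  (descriptors for ionized forms are future work, not present here).
* H_M_HBD and ΔG_tr_depol are inputs; the built-in fragment table is
  approximate by construction.
* The flexibility table is categorical, not a torsional-barrier
  calculation; bond classes without a stated value default to 1 and can be
  overridden per project.
* sp3 perception in exotic cases (strained small rings) follows rdkit's
  defaults.
* No regularized/robust regression, y-randomization, applicability-domain
  estimation or bootstrap intervals — deliberately out of scope.
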