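# Methods

## Scope and model

`crebind` analyses host-guest binding free energies over conformer
ensembles. The physical model is the standard one for semi-empirical
conformer-sampling workflows:

1. A molecule (free ligand, host, or 1:1 complex) is represented by an
   ensemble of structures, each carrying a total (electronic) energy and
   optionally a rigid-rotor harmonic-oscillator (RRHO) thermal correction
   and an implicit-solvation term, all in kcal/mol. Per-structure Gibbs
   energies are the sum `G = E + g_rrho + g_solv`.
2. Raw sampled ensembles are reduced to a conformer-rotamer ensemble
   (CRE): pairs of structures within the energy threshold are *duplicates*
   if their minimal RMSD is below the RMSD threshold, *rotamers* if their
   rotational constants agree to within the relative threshold but the
   RMSD does not, and distinct *conformers* otherwise. Retained structures
   must lie within an energy window of the global minimum.
3. Ensemble thermodynamics is discrete Boltzmann statistics over the
   retained structures: populations `p_i ∝ exp(-(G_i-G_min)/RT)`, average
   `⟨G⟩ = Σ p_i G_i`, partition-sum free energy
   `F = -RT ln Σ exp(-G_i/RT)`, conformational-rotational entropy
   `S_CR = -R Σ p_i ln p_i` and its free-energy term `G_CR = -T·S_CR`.
   The natural logarithm is required: with it, `F = ⟨G⟩ - T·S_CR` is an
   algebraic identity, which the code exploits as an internal consistency
   check (asserted to 1e-9 kcal/mol in tests).
4. Binding free energies for `host + ligand → complex` come in three
   flavors: best-pose difference (`dg_top`), population-averaged
   difference (`dg_ens`), and the entropy-corrected
   `dg_ens_tscr = dg_ens - T·ΔS_CR`, which equals the difference of the
   species' partition-sum free energies. No standard-state (1 M)
   correction is applied; the quantities mirror what association-energy
   workflows report. When every species has a single structure all three
   flavors coincide.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| temperature | 298.15 | K | aqueous-solution benchmark temperature |
| gas constant R | 1.98720425e-3 | kcal/(mol·K) | centralized in `constants` |
| energy threshold | 0.1 | kcal/mol | published defaults of iterative conformer samplers |
| RMSD threshold | 0.125 | Å | idem |
| rot.-const. threshold | 1 | % relative | idem; max over axes of \|ΔB\|/mean(B) |
| energy window | 6.0 | kcal/mol | retention window above the global minimum; staged refinement uses 15/10/6 |
| Hartree→kcal/mol | 627.5095 | — | tight-binding code convention |
| B(MHz) | 505379.0 / I(amu·Å²) | — | rotational-constant conversion |

RRHO thermochemistry uses Sackur–Tetrode translation (1 atm), the
classical linear/nonlinear rigid rotor, and quantum harmonic oscillators;
`g_rrho = ZPE + ΔH(T) - T·S_total` including the pV = RT term. The
rotational symmetry number defaults to 1 because symmetry-equivalent
images are carried explicitly as rotamers in the CRE rather than folded
into σ. No quasi-RRHO low-frequency damping is applied: corrections are
plain RRHO by design, and low-mode treatments would change none of the
discrete ensemble statistics that are the package's subject. The
frequency scaling factor defaults to 1.0.

Ensemble weights are computed from Gibbs energies when thermal terms are
available and electronic energies otherwise; which energies feed the
weighting is the caller's choice of `G` list, keeping the policy explicit.

## CRE assembly choices

Grouping is greedy in ascending energy order, which makes the result
deterministic and guarantees the global minimum is group 0's
representative. Each candidate is compared against group representatives;
a rotamer match is additionally deduplicated against the group's existing
rotamer members, otherwise repeated visits to one rotamer would
accumulate. Window pruning is applied last and is monotone: shrinking the
window never increases the retained count. Every dropped structure is
logged with a reason, so `retained + dropped = input` is checkable.

Mirror-image (improper-rotation) pairs are a deliberate consequence of
restricting superposition to proper rotations: a chiral structure and its
mirror have identical rotational constants and energy but non-zero minimal
RMSD, and are therefore classified as rotamers — matching how samplers
count enantiomeric images. No atom-permutation matching is attempted;
ensembles are assumed index-consistent, which is true of iterative
samplers that propagate one numbering.

## The synthetic torsional model

The generator stands in for a quantum-chemistry engine with a model whose
ground truth is enumerable. A bead chain of `n_torsions + 3` atoms with
fixed bond lengths (1.5 Å) and angles (109.5°) has energy

    V(φ) = Σ_t Σ_k a_{tk} (1 - cos(m_{tk} φ_t - δ_{tk}))
         + c Σ_t (1 - cos(φ_t - φ_{t+1})) + wall(centroid)

with Fourier amplitudes `a` (kcal/mol barrier heights), integer
multiplicities `m`, phases `δ`, optional nearest-neighbor coupling `c`,
and, in "complex mode", a polynomial ellipsoid wall
`w·max(0, q-1)^p` on the chain centroid (`q` the ellipsoid quadratic
form) emulating the non-covalent confinement cage of a host. Typical test
settings use barriers of 1.5–2.5 kcal/mol with 0.3–0.5 kcal/mol
asymmetries at T = 300 K — thermally accessible multi-minimum landscapes
comparable to single-bond rotations in drug-like molecules.

Sampling is Metropolis Monte Carlo in torsion space rather than
force-based dynamics: the RMSD-Gaussian bias
`V_bias = Σ k_i exp(-α Δ_i²)` needs only energies, and every claim the
tests make is distributional, not dynamical. `Δ_i` is the minimal
(Kabsch) RMSD in Å to the i-th deposited reference; `α` is taken per Å²
(the printed Bohr⁻¹ convention of the source workflows is dimensionally
a per-length² quantity; `constants.BOHR_TO_ANGSTROM` supports callers
converting from that convention). A snapshot is deposited as a new
reference on a fixed interval up to a cap; defaults
(k_push 0.25 kcal/mol, α 0.8 Å⁻², deposit every 50 steps, ≤30
references) put the accumulated bias on the scale of one barrier.
Recorded ensemble energies never include the bias; the per-snapshot bias
value and dwell time are attached to the returned ensemble so biased runs
can be reweighted by `exp(+V_bias/RT)`.

The brute-force oracle evaluates the torsional potential on a periodic
grid (≥36 points per torsion, ≤1e7 total points), finds local minima by
neighbor comparison, assigns every grid point to a basin by steepest
descent, and forms basin populations from the grid partition sum. This is
exact up to grid resolution (populations move <1% between 36 and 360
points on the test potentials) and is the independent reference for all
sampling checks.

What the generator does *not* emulate: real intramolecular force fields,
Cartesian dynamics and kinetics, bond/angle flexibility, solvation, and
quantum energetics. Passing the recovery tests therefore demonstrates
the correctness of the deduplication/weighting machinery, not the
accuracy of any electronic-structure method.

## Statistical validation design

Population recovery compares sampled to oracle populations within 3
Monte-Carlo standard errors. Estimates use 16 independent biased walkers
(6000 steps each; the first 1500 steps, during which the bias is still
being deposited, are discarded), each reweighted by dwell time and
`exp(+V_bias/RT)`; once deposition has finished the bias is static, so
the reweighting is exact for the post-burn-in samples. Standard errors
are taken *between* walkers: basin-switching autocorrelation within one
walker is long enough that within-run block standard errors are
unreliable, while between-replica errors are unbiased regardless of
autocorrelation. The metadynamics-enhancement check runs 20 paired seeds
of 600 steps on a double-well torsion with a ~5 kcal/mol barrier and
requires the biased walker to discover at least as many distinct minima
on average as the unbiased one.

Numerical frequencies solve the generalized eigenproblem
`H c = ω² G c` with a central-difference Hessian of the torsional
potential (step 1e-3 rad) and the kinetic metric
`G_ij = Σ_a m_a (∂r_a/∂φ_i)·(∂r_a/∂φ_j)` from embedding derivatives with
rigid-body translation/rotation projected out. At a maximum the negative
eigenvalues are reported as imaginary modes and raise.

## Numerical conventions and degenerate inputs

- Weights are computed from `G - G_min` (shift-invariant, no overflow);
  the partition sum uses `logsumexp`.
- Linear rotors are detected by a vanishing smallest inertia moment
  (relative tolerance 1e-10) and compared on their single finite
  constant; a linear/non-linear pair is maximally different.
- The 1°-grid superposition oracle scans a 10° Euler grid exhaustively and
  refines the five best candidates to 1° spacing; near the optimum the
  RMSD error is quadratic in the angular error, so grid error ≪ 1e-3 Å.
- `kabsch_rmsd` evaluates the fitted residual explicitly (not via the
  returned rssd) to avoid cancellation for near-identical inputs.
- Single-atom structures have RMSD 0 and no rotational constants (error);
  empty ensembles and empty free-energy lists raise.
- Benchmark SD is the population standard deviation of absolute
  deviations; displayed statistics round to 2 decimals while tests use
  explicit tolerances.

## Problem sizes

The shipped validation runs use two-torsion models, 6000-step walkers
(16 replicas), 600-step enhancement pairs, 1000-ensemble identity sweeps,
and 50 superposition pairs — sizes chosen so the full suite and the
acceptance script each complete in about a minute on one core while
leaving the Monte-Carlo standard errors small compared with the tested
effects.

## Known limitations

- No atom-permutation-aware RMSD: symmetric group re-labelling (e.g.
  methyl hydrogens) is treated as geometric difference.
- The staged 15/10/6 kcal/mol refinement re-assembles with constant
  thresholds by default; per-stage threshold tightening is supported but
  not exercised by the benchmark data.
- The pipeline's complex emulation shifts the toy complex ensemble by a
  constant binding offset; it makes no claim about pose geometry.
- External quantum-chemistry inputs (energies, frequencies, solvation
  terms) are consumed, never produced; there is no adapter that invokes
  an engine.
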