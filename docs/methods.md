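# Methods

`anhcascade` simulates equilibrium infrared spectra and time-resolved
hot-ground-state-cooling (HGSC) spectra of polyatomic molecules from
anharmonic vibrational data: per-mode frequencies ν_i, the symmetric
anharmonicity matrix **X**, and base IR intensities. This note records the
model, its assumptions, the numerical choices, and what the synthetic test
systems do and do not establish.

## Energy model

The energy of an occupation configuration **n** = (n_1, …, n_N) is the
second-order (Dunham/VPT2) expansion

    E(n) = Σ_i ν_i (n_i + 1/2) + Σ_{i≤j} X_ij (n_i + 1/2)(n_j + 1/2),

carried everywhere relative to the zero-point configuration,
E_rel(n) = E(n) − E(0). All energies are wavenumbers (cm⁻¹); temperature
enters only through k_BT = 0.695034800 cm⁻¹/K × T, and femtosecond rates
through ν·c with c = 2.99792458×10⁻⁵ cm/fs. An optional multiplicative
`freq_scale` (typically ≈0.99 when aligning computed frequencies with
solution spectra) applies to the frequencies only, not to **X**.

**Transition energies are computed by differencing E_rel**, not from a
separate closed-form expression. Differencing is self-consistent with the
energy model, covers fundamentals (n_i → n_i+1), first overtones
(n_i → n_i+2) and 1+1 combinations (n_i, n_j → n_i+1, n_j+1) uniformly,
and reduces to the closed forms

    ΔE_fund,i = ν_i + 2X_ii(n_i+1) + Σ_{j≠i} X_ij (n_j + 1/2)
    ΔE_ot,i   = 2ΔE_fund,i + 2X_ii
    ΔE_cb,ij  = ΔE_fund,i + ΔE_fund,j + X_ij

used by the vectorised hot loops (the closed forms are verified against
direct differencing in the test suite). Highly excited configurations can
produce non-positive transition energies; such lines always carry zero
intensity.

Line intensities scale the base (all-zero-configuration) intensities with
the harmonic-oscillator occupancy factors — (n_i+1) for fundamentals,
(n_i+1)(n_i+2)/2 for first overtones, (n_i+1)(n_j+1) for combinations —
and with the ratio ΔE/ΔE⁰ of the occupation-dependent transition energy to
its all-zero-configuration value. The occupancy scaling is exact only for
harmonic oscillators; it is the standard leading-order treatment. Base
overtone/combination intensities default to "absent" (no such lines) unless
supplied; the chromophore-like fixture assigns them a few percent of the
fundamental intensities so multi-quantum structure is exercised.

## State counting

The density of states ρ(E) that enters the multicanonical acceptance rule
treats the modes as separable anharmonic oscillators (X_{i≠j} = 0): each
mode contributes a ladder ε(n) = ν n + X_ii(n²+n), truncated at the last
strictly increasing level (beyond the anharmonic turnover the bound-state
expansion is meaningless) and at the energy ceiling. The Stein–Rabinovitch
direct count convolves the ladders mode by mode on an internal grain
(default 1 cm⁻¹) and aggregates to the requested bin width (default
16 cm⁻¹, half-open bins [b·w, (b+1)·w) relative to the zero point).

With ~90 modes at ~1 eV the counts exceed 10²⁰, far beyond int64, so they
are held as arbitrary-precision Python integers; Boltzmann weighting
(counts × e^{−E/kT} on bin centres) is evaluated in log space.

Two accuracy remarks. First, grained counting is exact whenever every
ladder energy is an integer multiple of the grain — the fixture generators
emit integer-cm⁻¹ frequencies and diagonal anharmonicities, so the
brute-force equivalence tests are exact integer comparisons; for
incommensurate input the placement of individual states is accurate to the
grain. Choose the grain to divide the bin width. Second, a brute-force
enumerator with the full **X** (candidate ranges from the separable ladders
plus a cross-term slack margin, guarded by a configurable cap) serves as
the oracle for small systems.

## Multicanonical sampling

The equilibrium spectrum at temperature T is assembled from a
flat-histogram random walk over occupation space. Per step every mode
independently proposes −1 with probability s/N and +1 with probability
s·r/N (defaults r = 1.08, which biases the walk toward the
entropically-sparse high-energy side; s = 1 for N ≥ 3 and is shrunk
automatically for smaller systems, where 1/N-scale probabilities would be
improper — the Hastings ratio is unchanged because s cancels). Decrements
at n_i = 0 are suppressed. A proposal is valid only if E_rel stays inside
the current energy window and every fundamental keeps ΔE > 0; valid
proposals are accepted with

    p_acc = min[1, ρ(E)/ρ(E_prop) × g_rev/g_fwd],

where the generation-probability ratio equals r^Δn (Δn = current −
proposed total quanta) for this proposal family, including at the n_i = 0
boundary (unmoved modes contribute identical stay probabilities to both
directions, and a realised down-move always has an allowed reverse
up-move). The stationary law is therefore uniform within each energy bin.

Regardless of acceptance, the histogram bin of the current energy is
incremented and the current configuration's stick spectrum is accumulated
(nearest wavenumber bin) into the corresponding spectral row. The walk
stops when all reachable bins satisfy |H_b − ⟨H⟩|/⟨H⟩ < α (default 0.25).
Reachability is separable-ρ > 0 *and* visited: with a full **X** matrix a
few ρ > 0 bins near bin edges can hold no valid configuration (the
separable and full energies bin differently), and a flatness test that
waits for them would never terminate; the visited set must additionally be
stable between consecutive flatness checks before the test can pass. For
the same reason the histogram over a toy system with sizeable off-diagonal
couplings converges to ρ_true/ρ_sep rather than to a constant; at a
realistic mode count the per-bin mismatch is negligible.

The energy range of interest (≈1 eV by default) is split into
non-overlapping windows (default four) sampled by independent walks
(default six per window) from random valid initial configurations. Rows
are pooled across walks sample-weighted, divided by their sample counts,
concatenated across windows, and summed with Boltzmann bin weights to give
the canonical stick spectrum; Gaussian convolution (area-preserving,
default 5 cm⁻¹ FWHM) is applied only at presentation time.

## Kinetic Monte Carlo cooling

Vibrational cooling to the solvent is modelled as single-quantum exchange
with an isothermal bath at T_bath (default 300 K). Per step of dt
(default 5 fs) mode i proposes a downward step with probability
p_down,i = q_i n_i ν_i c dt and an upward step with
p_up,i = q_i (n_i+1) ν_i c dt e^{−ν_i/k_BT}. The dimensionless q
(default 0.1, per-mode overridable) is the model's single adjustable
parameter; it scales the clock only. Proposal draws use the step-start
occupations; proposed moves are visited in random order (avoiding index
bias) and accepted per single-quantum move with the energy recomputed
after each accepted move. Occupation validity bounds are deliberately not
enforced: projected nascent configurations may start outside the
expansion's valid range and must be able to relax. Probabilities that
would exceed 1 are clipped with a warning (a sign dt is too large).

Three acceptance conventions are available. `as_printed`
(min[1, e^{−(E−E_prop)/k_BT}]) is the package default. Note its behaviour:
it *penalises* downward (cooling) moves by e^{−ΔE/k_BT} and accepts upward
moves freely. Because the Boltzmann factor already sits inside p_up, the
proposal rates alone satisfy detailed balance in the harmonic limit
(up(n→n+1)/down(n+1→n) = e^{−ν/k_BT}, the Bose–Einstein stationary state),
and the extra factor merely slows every mode's kinetics by e^{−ν_eff/k_BT}
— a mode-dependent slow-down of order 10³ for a 1570 cm⁻¹ mode, which a
q ≈ 0.1 calibration cannot offset. `metropolis` is the sign-flipped
convention; it damps upward moves twice and equilibrates below the bath
temperature. `none` (always accept) leaves the detailed-balance-correct
proposal rates untouched and is the convention used by the cooling
demonstrations and validation runs in this package; all three remain
selectable because the "right" reading is genuinely ambiguous.

Every trajectory stores the current configuration's stick spectrum into
the row of its time step regardless of acceptance; many trajectories
(default 576; the validation runs use 48–64) are averaged per initial
configuration. A thermal configuration (independent per-mode geometric
draws at T_bath) can be added element-wise to each hot configuration,
resampled per trajectory. Difference spectra are formed by subtracting an
equilibrium row.

## Initial conditions

*Surface-hopping projection.* A hop geometry is superimposed on the
equilibrium reference (mass-weighted Kabsch; without this, overall
rotation/translation would contaminate the projections — exactly invariant
identities hold only in the reference Eckart frame, and the tests check
both regimes). The mass-weighted displacement is projected onto the
orthonormal mass-weighted normal vectors, q_i = L_i·Δx̃, and per-mode
harmonic energies e_i = 0.0148302·ν_i²q_i² (cm⁻¹ for q in √amu·Å) define
partition weights. The released electronic energy is distributed over the
modes proportionally to e_i and converted to integer quanta by
largest-remainder rounding, so Σ n_i ν_i matches the released energy to
within one quantum of the largest populated mode. An alternative
`direct` strategy rounds e_i/ν_i per mode without renormalisation.
Velocities at the hop are ignored.

*Thermal sampling* uses independent per-mode geometric distributions
P(n_i) ∝ e^{−n_iν_i/k_BT} (harmonic weights; at ambient temperature and
mid-IR frequencies the anharmonic correction is negligible, and the
multicanonical path exists where exactness matters).

*Rapid-exchange statistical configurations* are drawn uniformly from the
configurations whose E_rel falls in the 2·tol-wide energy bin containing
each target. A walk confined to the band would be reducible —
single-quantum moves cannot connect most same-energy configurations
without passing through other energies — so the draw runs the
multicanonical walk (r = 1) over [0, band top) and records the state when
it sits in the target bin; uniformity within the bin is inherited from the
flat-histogram stationary law and is verified against enumeration.

## Band analysis

Band metrics operate on spectrum rows: trapezoidal integration over a
window, and the band expectation frequency ⟨ν⟩ = ∫νS dν / ∫S dν, whose
rise in time quantifies hot-band reshaping. ⟨ν⟩ is defined on net-positive
intensity only; a bleach-dominated (net-negative) window raises rather
than returning a sign-corrupted mean.

Integrated signals are fitted to the sequential first-order scheme
S1 →(τ1) S0* →(τ2) S0 with S1 = e^{−k₁t},
S0* = k₁/(k₂−k₁)(e^{−k₁t} − e^{−k₂t}) (limit form k t e^{−kt} engaged for
|k₂−k₁| < 3×10⁻⁴k₁), S0 = 1 − S1 − S0*, all components zero for t < 0 and
optionally convolved analytically with a Gaussian instrument response.
Because S1 + S0* + S0 ≡ 1, a free ground-recovery amplitude is perfectly
collinear with the baseline and the other amplitudes; the fit therefore
works in the identifiable basis {1, S1, S0*} and reports the absorbed
parameterisation. Lifetimes are bounded positive; τ standard errors are
withheld (and the fit flagged unidentifiable) when the numerical Jacobian
at the optimum is rank-deficient or the kinetic amplitudes vanish, e.g.
for a constant trace.

## Synthetic systems

No real molecule's anharmonic data are shipped; every test input is
generated by seeded, counter-based (Philox) random streams, so outputs are
bit-reproducible across platforms.

*Toy systems* (1–4 modes) draw integer frequencies and integer negative
diagonal anharmonicities (commensurate with the state-count grain, hence
exact oracles) plus optional small off-diagonal couplings, and regenerate
until all ground-state fundamentals are positive.

*The chromophore-like system* mimics the structure of a mid-size
conjugated photoswitch: 87 modes spanning ≈50–3200 cm⁻¹ in four blocks
(torsions, fingerprint, double-bond stretches, X–H stretches); two
dominant marker bands whose cold fundamentals are placed at 1570 cm⁻¹
(C=C stretch analogue, base intensity 100) and 1465 cm⁻¹ (bridge C–C
analogue, 60); a 14-mode active subset (the markers plus low/mid-frequency
partners) representing the modes energised by the isomerisation;
self-anharmonicities ≈0.5% of the frequency (markers −4.0/−3.5 cm⁻¹ so
singly-excited hot lines stay inside the analysis windows); and
all-negative mode–mode couplings, an order of magnitude stronger within
the active set (≈−0.8 cm⁻¹) than to spectators (≈−0.1 cm⁻¹), so exciting
the molecule red-shifts the markers and cooling blue-shifts them back.
Marker frequencies are re-centred after coupling assignment so the cold
fundamentals land exactly on the nominal positions. Hot configurations
distribute quanta over a chosen mode subset until the harmonic energy sum
is within half a quantum of the target.

What passing tests on these fixtures establish: the samplers, counters and
kinetics are mutually consistent and reproduce their exact small-system
limits, and the cooling model produces the qualitative HGSC phenomenology
(energy decay to the thermal plateau, monotone noise-bounded marker
blue-shift toward the equilibrium band position, distinguishable
trajectories for projection-style vs statistical initial conditions). They
do not establish quantitative accuracy for any real molecule — that
requires real VPT2 frequencies, **X** and intensities as input — and they
cannot probe resonance-polyad effects, solvent shifts or mode-specific
IET, which are outside the model.

## Problem sizes and numerical defaults

The validation suite and `scripts/acceptance.py` use desk-scale settings
chosen to keep each experiment well-converged at interactive runtimes:
20 random systems for the counting oracle; 3-mode toys (≤200 states) with
2 energy windows and 3 walks (≤3×10⁵ steps each) for the multicanonical
checks; 10⁶ steps for the single-mode bath equilibrium; and 48–64
trajectories × 2000 steps (10 ps at dt = 5 fs) × 4 initial configurations
per family for the 87-mode cooling runs. Flatness uses α = 0.25 with
checks every 500 steps; visitation statistics thin the chain (every 200th
step) so χ² sees approximately independent samples. Tolerances asserted in
tests are stated next to each assertion; Monte-Carlo comparisons use 3σ
bounds from batch means or analytic ensemble spreads.

## Known limitations

- The separable ρ(E) biases flat-histogram visitation where off-diagonal
  couplings move states across bin edges (immaterial at realistic mode
  counts; quantified on toys in the test suite). Configurations whose
  full-**X** energy falls in a separable-ρ = 0 bin are unreachable by the
  sampler and excluded.
- Intensity occupancy scalings are harmonic-oscillator approximations;
  anharmonic intensity sharing (resonance polyads) is upstream of this
  package.
- The cooling model has no explicit intramolecular redistribution; q
  subsumes IVR and IET into one rate scale, and q itself must be
  calibrated against experiment.
- The hop-energy partition (proportional to harmonic displacement energy)
  is one defensible reading of energy projection; the strategy interface
  accepts alternatives.
- `as_printed` acceptance slows cooling by mode-dependent Boltzmann
  factors (discussion above); quantitative time scales in this package's
  demonstrations are produced with `acceptance_mode="none"`.
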