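# Methods

This note records the models implemented, the defaults chosen where the
standard formalism leaves freedom, and what the synthetic test corpus
does and does not establish.

## Dose chain

The package implements the MIRD-schema chain for one nuclide at a time:
emission spectrum → S values → time-integrated activity (TIA) →
absorbed-dose coefficients → effective dose. Decay-chain progeny are
not followed; none of the implemented equations includes ingrowth, and
a daughter nuclide is handled, if needed, as a separate run.

**Emissions.** Each emission line carries a type (photon, electron,
beta±, alpha), an energy in MeV and a yield per transformation. Beta
transitions are represented by their mean energy carrying the full
transition yield; spectrum-bin rows (one row per bin with per-bin
intensities) are also accepted and flow through the Δ = E·Y formalism
identically. Neither convention is privileged — the energy-weighted sum
is what enters the S value. Radiation weighting is w_R = 1 for every
type used diagnostically (alpha carries 20 but never appears in the
intended use); w_R is applied at the effective-dose stage, not inside
S values, so S values remain pure absorbed-dose quantities.

**SAF interpolation.** Specific absorbed fractions are tabulated per
(target ← source, radiation type) on strictly increasing energy grids.
Between grid points the lookup is log–log linear, the convention for
the smooth, roughly power-law energy dependence of SAFs; on intervals
where an endpoint is zero the log transform is undefined and the
fallback is linear interpolation in linear space. Below the lowest
simulated energy the value at that cutoff energy is used — a
deliberately conservative (dose-overestimating) policy for soft
emissions at large source–target distances. Above the grid the
highest-energy value is used; only the low side has a physically
motivated convention, so both out-of-grid policies are overridable
(`SAFPolicy`). Electrons use their own SAF entries like photons; no
local-absorption shortcut is applied to charged particles.

**Unit convention.** Internal arithmetic is SI: TIA in hours, S values
in Gy per transformation (1 MeV = 1.602176634×10⁻¹³ J). The published
convention mGy/MBq (and mSv/MBq after weighting) is applied exactly
once at the dose boundary: 1 h of TIA per MBq administered is
3600 s × 10⁶ decays/s = 3.6×10⁹ transformations, and Gy → mGy adds
10³, i.e. a net factor 3.6×10¹².

## Biokinetic adjustments

TIA entries are sums of exponentials (rates include physical decay) or
directly tabulated cumulated activities. The adjustment rules are
applied in a fixed order — integration, bladder voiding, GI transit,
legacy-colon conversion, bone partition, blood distribution, residual —
and every rule logs an audit line into the TIA vector's provenance.

**Bladder voiding.** The urine input is given as the bladder-content
curve in the absence of voiding, f(t). Between voids the standing
content changes only by inflow and physical decay, so the content
removed at a void would subsequently have decayed purely physically;
the TIA is therefore ∫f − Σ_v B(t_v⁻)/λ_phys with the pre-void
contents obtained recursively, iterated until a cycle contributes less
than 10⁻¹² of the total. The default voiding interval is 3.5 h with
the first void at 3.5 h; it is a configuration default (not a physical
constant) and overridable per call and per batch config. The integration
horizon defaults to infinity, where every term has a closed form;
finite horizons are supported for comparisons against tabulations.

**Colon conversion.** Activity assigned to the legacy upper/lower
large-intestine regions is reassigned to the alimentary-tract colon
segments by the fixed mass-based factors right = 0.71·ULI,
left = 0.29·ULI + 0.56·LLI, rectosigmoid = 0.44·LLI. The factor pairs
sum to one, so the conversion conserves TIA exactly; wall entries map
to wall segments and content entries to content segments.

**GI transit.** Beyond the colon reassignment, gastrointestinal
excretion is modelled as a first-order catenary chain over the
alimentary segments with configurable mean residence times. The
defaults (stomach 0.75 h, small intestine 4 h, 12 h per colon segment)
are fixture-grade values in the spirit of the alimentary-tract model,
chosen once for realism; they are labelled defaults in config and logs
and are not a reference tabulation. With transfer rates k_i = 1/MRT_i
and decay λ, the fraction reaching segment i is Π_{j<i} k_j/(k_j+λ)
and each unit entering contributes 1/(k_i+λ) hours — closed form, no
ODE solver.

**Bone.** When the cortical/trabecular split is unknown, substances
with an effective half-time strictly shorter than 15 days are
surface-deposited, otherwise volume-deposited; exactly 15 days is
volume ("shorter than" is strict). Surface TIA splits 50/50 between
trabecular and cortical by default; volume TIA splits
mass-proportionally when phantom masses are available, else 50/50. An
explicitly known split is always used verbatim.

**Blood.** Circulating-blood TIA distributes over regions by their
fractional blood content; the unassigned residue joins the "other
organs and tissues" pool. A substitution map covers sources absent
from the SAF compilation (e.g. heart contents standing in for the
aorta); substitutions are applied before any remainder arithmetic and
recorded in the S-value matrix provenance.

**Residual.** When a total-body curve coexists with organ curves, the
organ TIAs are subtracted from the total-body TIA and the difference
becomes the source "other organs and tissues". Small negative
residuals (a known artefact of rounded tabulations) are floored at
zero with a warning rather than treated as errors. The corresponding
S value is the formally exact remainder solution
(m_TB·S(T←TB) − Σ_s m_s·S(T←s)) / (m_TB − Σ_s m_s), with the
accounted-source list equal to the model's explicit TIA sources — not
all phantom sources. Negative remainder S values, possible only with
inconsistent inputs, clamp to zero with a logged warning so batch runs
survive bad entries while surfacing them.

Every resolved TIA vector is checked against the physical bound
Σ Ã ≤ T_phys/ln 2: no kinetic model can accumulate more
transformations than pure physical decay of the whole administered
activity.

## Effective dose

**2007 scheme.** Named weights 0.12 (red marrow, colon, lungs, stomach
wall, breast, remainder), 0.08 (gonads), 0.04 (bladder wall,
oesophagus, liver, thyroid), 0.01 (bone surface, brain, salivary
glands, skin); the remainder is the equal mean over 13 tissues per sex
(adrenals, extrathoracic region, gall bladder wall, heart wall,
kidneys, lymphatic nodes, muscle, oral mucosa, pancreas,
prostate/uterus, small intestine wall, spleen, thymus). Each sex's
equivalent doses are weighted separately and the Reference Person
value is the arithmetic mean of the two, so E_ref = (E_male+E_female)/2
holds exactly by construction. A sex-specific tissue contributes the
available sex's dose (gonads average testes with ovaries as one
tissue); a tissue missing from both sexes is an error.

**1990 scheme.** Weights 0.20 (gonads), 0.12 (red marrow, colon,
lungs, stomach wall), 0.05 (bladder wall, breast, liver, oesophagus,
thyroid, remainder), 0.01 (skin, bone surface), applied to organ doses
first averaged between the sexes. The remainder takes the
mass-weighted mean dose over a configurable tissue list (default:
adrenals, brain, small intestine wall, kidneys, muscle, pancreas,
spleen, thymus, uterus, upper large intestine — the historical list is
not uniquely fixed, so it is a parameter). Splitting rule: if one
remainder tissue receives a higher dose than every named tissue, half
the remainder weight (0.025) applies to that tissue and half to the
mass-weighted mean of the rest. Some secondary literature quotes the
half-weight as "0.25", which conflicts with the remainder weight of
0.05 itself; this implementation uses half of 0.05. The composite
colon dose feeding the colon weight is the mass-weighted mean of the
right/left/rectosigmoid colon wall doses using wall masses (the dose
targets are walls; content masses would weight the sources instead).

Both packaged schemes validate Σ w_T = 1 in exact decimal arithmetic
at load time.

## Reporting conventions

Percent differences against published coefficients are integers rounded
half away from zero, computed in decimal arithmetic so printed
coefficients landing exactly on a .5 boundary round deterministically
(−7.5 → −8). Exported coefficients use three-significant-figure
E-notation (e.g. `1.59E-02`). The difference histogram defaults to
10-percentage-point bins spanning −100 % to +100 % with explicit
under/overflow buckets; the bin width is a chosen default, not a
convention. Collective-dose rescaling accepts an aggregate new/old
ratio, a per-exam-category table, or a directly known new total, and
reports the integer percent reduction under the same rounding.

## Synthetic corpus and what the tests show

The fixture generator emulates the *structure* of real inputs — a
wall/content region catalogue with the seven alimentary segments and a
bladder pair, sex-specific gonads, blood-content fractions, SAF grids
over 0.01–1 MeV — with seeded randomness (bit-identical files per
seed). SAF magnitudes are made physically coherent by construction:
per source and energy, target shares are drawn from a Dirichlet
distribution under a budget so Σ_T φ(T←S,E) ≤ 1, electron shares are
tilted toward self-absorption, and the total-body source rows are the
mass-weighted combination of the per-source rows, which makes a
uniform S column an exact fixed point of the remainder formula.
Biokinetic archetypes cover each adjustment rule (bladder, GI, bone
short/long, blood pool, legacy gut, total-body residual).

What passing tests show: the arithmetic of every stage is correct
(engine vs independent triple-loop oracle to ~10⁻¹⁵ relative on 100
seeded fixtures; closed-form and hand-computed cases per rule), the
conventions are applied as documented, and the chain is deterministic.
What they do not show: agreement with any reference compilation's
actual SAF values, organ masses or biokinetic tables — the corpus is
synthetic, and absolute coefficients computed from it carry no
physical meaning. Published-coefficient checks in the test suite and
acceptance script therefore exercise the comparison and sex-averaging
machinery on printed values rather than re-deriving those values from
non-bundled reference data. Fixture problem sizes (18–41 regions,
3–4 emission lines, 4–5 grid energies, 25–100 seeds) were chosen to
exercise every code path while keeping the suite fast.

## Numerical choices and edge cases

- Log–log interpolation falls back to linear only on intervals with a
  zero endpoint; lookups at grid energies return tabulated values
  bit-exactly, and repeated queries are bit-identical.
- Bladder cycle iteration stops when the un-voided content curve
  contributes less than 10⁻¹² of the total, with a hard cycle cap.
- Known-split and surface fractions must sum to 1 within 10⁻⁹.
- Duplicate identical decay rows parse with a warning (kept); duplicate
  SAF grid points are an error.
- Region names normalize case/separator-insensitively against a
  canonical catalogue with aliases (e.g. "red bone marrow" → "red
  marrow"); unknown names fail with nearest-match suggestions.
- Batch entries fail individually without aborting the run; failures
  are collected, logged and marked in the comparison table.

## Known limitations

- One nuclide per computation; no progeny ingrowth.
- No Monte Carlo transport: SAFs are inputs, never recomputed.
- The four-compartment bone model ignores skeletal fine structure.
- The GI chain is first-order with fixed mean residence times; no
  age-, meal- or sex-dependent transit beyond supplying different
  per-sex TIA inputs.
- The 1990 remainder list and the alimentary residence times are
  defaults, not authoritative reference values.
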