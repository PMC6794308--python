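# Methods

## Mixed-layer dissolved-gas model

Both rate estimates treat the mixed layer as a single box at steady state
with negligible mixing and advection: production, respiration and air–sea
exchange balance.  Under these assumptions the dissolved ¹⁷Δ is set by the
competition between the photosynthetic source (end-member ¹⁷Δ_photo) and
gas exchange relaxing the pool toward air equilibrium (¹⁷Δ_eq), giving

GPP = k·[O₂]eq·(¹⁷Δ_diss − ¹⁷Δ_eq)/(¹⁷Δ_photo − ¹⁷Δ_diss),

while the biological O₂/Ar supersaturation fixes NCP = k·[O₂]eq·Δ(O₂/Ar).
Negative NCP (net heterotrophy) is reported with its sign.  A time-dependent
or entraining mixed layer is out of scope; when the steady-state
precondition fails (¹⁷Δ_diss at or above the photosynthetic end-member) the
code raises rather than extrapolating.

Isotope constants: λ = 0.518; ¹⁷Δ_photo = 249 per meg, ¹⁷Δ_eq = 8 per meg,
equilibrium δ¹⁸O = 0.73 ‰ vs atmospheric O₂.  These end-members are
standard literature values, not quantities this package derives; they are
stored in config precisely because different laboratories adopt slightly
different ones, and any such choice propagates linearly into GPP.

## Gas exchange

Piston velocity uses the quadratic wind-speed parameterization
k = a·u10²·(Sc/660)^(−1/2) with a = 0.251 cm h⁻¹ (m s⁻¹)⁻², the Schmidt
number from a 4th-order polynomial in temperature for seawater, and O₂
solubility from the Garcia–Gordon (Benson–Krause) fit in ml L⁻¹ converted
with 22.3916 ml mmol⁻¹.  All fits live in config, not in logic.

Because the gas signatures integrate over the mixed layer's flushing time,
station k is a weighted mean over the wind history: counting backwards from
the sampling day, day *i* ventilates f_i = min(1, k_i·Δt/z_ml) of the layer
and receives weight ω_i = f_i·∏_{j<i}(1−f_j), renormalized to sum to one.
The cap at 1 prevents negative weight products under strong winds over a
shallow mixed layer.  The window defaults to 60 days — after several
flushing times the surviving weight is negligible, so the result is
insensitive to the exact value; it is exposed in config.  A fully calm
window degenerates to uniform weights.

Monte Carlo uncertainty propagation perturbs each measured input with
independent Gaussian noise of its stated σ (default 1000 draws, seeded);
inputs are treated as uncorrelated, which matches how the measurement
errors are quoted.

## ¹³C incubation rates

Per bottle, rate = [(atom%_PC,final − atom%_PC,natural)/(atom%_DIC −
atom%_PC,natural)]·[PC]/Δt; the mean dark rate is subtracted from the mean
light rate.  Natural-abundance atom% defaults to 1.1.  Negative net rates
are reported unless explicitly floored.  Depth integration is trapezoidal
with linear interpolation at interior bounds and no extrapolation
(µM·m ≡ mmol m⁻²).

## Stoichiometric budget

`derive_stoichiometry` counts the electrons liberated by complete oxidation
of C_aH_bO_cN_dP_e to CO₂, H₂O, NH₃ and H₃PO₄ (E = 4a + b − 2c − 3d + 5e)
and assigns them to nitrate at 5 e⁻ per N reduced to N₂, so HNO₃ demand is
E/5 and N₂ yield E/10; water closes the hydrogen balance and a residual
check verifies all five elements to 1e-9.  Organic N leaves as NH₃.  The
anammox pairing option debits one nitrite from the oxidized-N pool per NH₃
(1:1), so each released NH₃ contributes two N to total N loss; the toggle
exists for sensitivity analysis, and for N-free matter it has no effect.

Budget chain: consumed C flux is the difference of trap fluxes bracketing
the ODZ (negative differences are reported as in-situ production signals,
never clipped); an export scale (default 2, from the literature estimate
that total organic fluxes are 2–3× trap fluxes) converts trap-derived to
total consumption; a consumed-fraction (default 1.0) times the scaled flux
is respired uniformly in a 200 m layer (the upper ~30% of the ODZ, where
N₂ production concentrates), giving nM N d⁻¹; accumulation multiplies by a
3.9 yr residence time at 365.25 d yr⁻¹.  Rounding to integer nM or µM
happens only at report time.  The published 4–6 nM N d⁻¹ spread corresponds
to different consumed-fraction/scale settings; the defaults reproduce the
lower endpoint, and the upper endpoint follows from scaling (e.g. export
scale 3 with consumed fraction ~1).

The measured station profile differences to 0.27 mmol C m⁻² d⁻¹ (and
26 µmol N m⁻² d⁻¹) between 105 and 150 m, though these quantities are often
quoted as 0.26/25 — rounding applied to unrounded source measurements; this
package always reports unrounded differences.

## Placement quantification

Filtering removes placements with pendant branch length > 2.0 (spot checks
in the source data showed such reads belong to other genes) and reads
shorter than 100 nt (33 aa).  The e-value cutoff (<10⁻⁵) applies upstream
during read recruitment and is carried as provenance only.  Normalized
abundance is count/(library size × gene length)×100, then divided by the
clade's marker copy number; the ×100 is cosmetic and commutes with the
copy-number division (we apply ×100 first).  Gene lengths are reference
alignment lengths, in aa for protein markers and nt for the ITS, recorded
with their unit to prevent silent mixing.  Paired reads placed as one
record are collapsed by read id, keeping the placement with the highest
weight; ties break deterministically toward the lexicographically smaller
clade label with a logged warning (the placement format does not encode
tree depth, so "more basal" is approximated by a stable ordering).
Virus/host ratios use length-normalized abundances, not raw counts,
because the two marker genes differ in length.  jplace ingestion takes a
user-supplied edge→clade table; the flat TSV dialect bypasses it.

Peptide-overlap statistics are set operations on identified peptide
sequences per sample, optionally restricted to a source taxon; Venn-style
partition fractions over a set of comparison samples sum to one.

## Synthetic study conditions

The generator emulates one offshore oligotrophic ODZ station: 60 days of
lognormal trade winds with mean 7 m s⁻¹ (log-σ 0.25, mean-corrected —
positive and right-skewed like satellite wind records); a 25 m mixed layer
at 27 °C / 34.5; true GPP 60 and NCP 3 mmol O₂ m⁻² d⁻¹ (mid-range offshore
values); traps at 105/150/750 m with 0.39 mmol C m⁻² d⁻¹ background and
0.27 mmol C m⁻² d⁻¹ injected at 150 m, the combined flux attenuating below
with a Martin exponent of 0.41 so the profile area-matches the measured
0.39/0.66/0.34; a four-clade cyanobacterial community dominated by
*Prochlorococcus* LLIV/V; a free-living virus/host ratio of 35 (inside the
observed 30–40 band); 1.2% of marker reads given branch length 3.0
(mid-range of the 0.1–2.5% removal rate observed in real libraries).
Measurement noise defaults: σ(δ¹⁷O) = 0.002 ‰, σ(δ¹⁸O) = 0.004 ‰
(≈3 per meg combined on ¹⁷Δ, giving ~15% GPP uncertainty, matching the
precision of reported rates), σ(Δ(O₂/Ar)) = 0.001; trap-flux noise off by
default because the real deployments were single measurements.

The gas generator is the algebraic inverse of the productivity equations,
so noise-free round trips recover truth to machine precision — that tests
the algebra, not the realism of the box model.  The generators do not
emulate vertical structure within the mixed layer, correlated measurement
errors, placement uncertainty (each synthetic read has a single placement),
chimeric reads, or peptide false discoveries; passing tests therefore
demonstrate correctness of the computational chain and its statistical
calibration under the stated error model, not robustness to those
real-data pathologies.

## Problem sizes

Property suites run 1000 random organic-matter formulas; community-recovery
checks draw 10⁵ marker reads; noise-calibration compares a 2000-draw Monte
Carlo against 200 regenerated stations.  These sizes put multinomial and
Monte Carlo standard errors well below the tolerances being checked.

## Known limitations

Single-box steady-state gas budget (no entrainment, advection or bubble
injection); residence time and export scale are inputs, not modeled; the
stoichiometry assumes complete oxidation with nitrate as sole acceptor (no
N₂O intermediates, no sulfur-driven chemolithotrophy); clade assignment
takes the single best placement rather than spreading weight across
placements.
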