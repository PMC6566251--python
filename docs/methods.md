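# Methods

## Model

pycomsia implements similarity-index 3D-QSAR. Aligned molecules are
sampled on a shared cubic lattice; at each grid point and for each of
five fields the descriptor is a Gaussian-attenuated similarity to a
unit probe,

    A_k(q) = − Σ_a  w_probe,k · w_a,k · exp(−α r_aq²),

so values are smooth, bounded by Σ|w| and vanish away from the
molecule; unlike Lennard-Jones/Coulomb fields there are no
singularities at atomic positions, and no distance cutoff is required.
The leading minus sign is the field-engine sign convention used
throughout; consequently steric, donor and acceptor columns (whose
atomic weights are non-negative) are everywhere ≤ 0.

Activity is modeled by PLS1 (NIPALS) on the column-centered descriptor
matrix and centered pIC50. No per-column variance scaling is applied:
the fields enter on their natural similarity-index scale, and
field-contribution estimates are computed on that same scale as the
normalized per-field sum of |coefficient| × training-column sd.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| lattice spacing | 2.0 | Å | conventional resolution for field QSAR; halving it quadruples columns with little statistical gain |
| lattice margin | 4.0 | Å | extends the union bounding box so Gaussians (α = 0.3 ⇒ ~1.3 Å length scale) decay inside the box; configurable, recorded in provenance |
| attenuation α | 0.3 | Å⁻² | standard similarity-field attenuation |
| probe weights | +1 charge, 1 Å radius, +1 hydrophobicity, +1 donor, +1 acceptor | — | the conventional unit probe |
| steric atomic weight | r_vdw³ | Å³ | the cube convention; the Bondi radius table ships in `params.py` and is swappable |
| min_sigma column filter | 0.01 | similarity-index units | removes near-constant columns (computed on training rows only); not an imitation of any commercial default |
| max components | 20 | — | LOO scans 1..20; published field-QSAR models reach N ≈ 19 |
| component selection | argmax q², ties → smaller N | — | the standard "optimum number of components" rule |
| AD threshold | 3.0 | training sd units | the standardization rule: inside if all s ≤ 3, outside if all s > 3, else inside iff mean(s) + 1.28·sd(s) ≤ 3 |

Internal statistics use the conventions
q² = 1 − PRESS/Σ(y−ȳ)², SEP = √(PRESS/(n−c−1)),
SEE = √(RSS/(n−c−1)), F = (r²/c)/((1−r²)/(n−c−1)); the n−c−1
denominator was chosen because it reproduces published F arithmetic
from (r²_ncv, n, c) triples to within rounding (see
`tests/test_pls.py::TestStats`).

## External-validation conventions

The through-origin slope k is predicted-on-observed
(Σyŷ/Σy²) and k′ its mirror; r′₀² = 1 − Σ(y−k′ŷ)²/Σ(y−ȳ)² and r₀²
the mirrored convention with Σ(ŷ−ŷ̄)² in the denominator. These
assignments were fixed once by checking which convention reproduces the
packaged reference table's printed slopes, and both conventions are
always emitted under explicit labels. r²m is computed in its
square-root form r²·(1−√|r²−r₀²|); the linear variant (no square root)
is also reported (`rm2_linear`) because both appear in print. Q²_F3's
denominator is the training-set activity variance (the internally
consistent standard definition). Q²_F1/F2/F3 and CCC follow their
usual definitions; CCC ≤ |Pearson r| always (property-tested).

Known discrepancy: from the packaged table's rounded values the
reference r²m (printed 0.723) and Δr²m (0.056) are not reproduced
exactly by either convention (we obtain 0.757 and 0.064); they are
reported, tested at a wider ±0.06 band, and not silently adjusted.

## The synthetic generator

`GeneratorSpec` states a small rigid congeneric series: a fixed
8-pseudo-atom scaffold (planar hexagon + two out-of-plane anchors,
shared exactly by every compound, hence pre-aligned) and three
substituent sites whose atomic properties are drawn per compound —
charge U(−0.5, 0.5), vdW radius U(1.4, 2.0) Å, hydrophobicity
U(−1, 1), donor/acceptor flags with probability 0.3. Activity is a
planted linear functional of the compound's true field values at the
site positions (default: electrostatic only, weight 2.0, giving an
activity spread of roughly one log unit) plus N(0, 0.3²) noise and a
7.0 baseline — matching a typical pIC50 series midpoint, spread and
assay noise. The generator computes its field terms with its own local
closed-form sum, independent of the field engine it is used to test.

What a green recovery test establishes: the engine + PLS pipeline can
find a planted linear field–activity relation at realistic
noise-to-signal, attribute it to the correct field, and predict held-out
compounds to within twice the noise sd. What it does not establish:
behavior on real valence chemistry (conformational flexibility,
correlated substituent effects, charge-transfer), alignment ambiguity,
or activity cliffs — the generator's molecules are rigid pseudo-atom
constructs and its effects are exactly linear.

## Numerical choices

- NIPALS deflation stops early if the weight or score norm falls below
  1e-12 (rank exhaustion); requesting more components than the rank
  supports is an error in `fit_pls` and a silent cap in the LOO scan.
- LOO refits once per left-out compound; coefficients for every
  intermediate component count come from the same deflation pass, which
  is what makes the 31-subset combination scan affordable.
- Kabsch superposition uses SVD with a determinant sign correction so
  the rotation is always proper; fewer than 3 pairs or collinear point
  sets raise a degenerate-geometry error rather than returning an
  arbitrary rotation.
- Donor/acceptor typing needs connectivity: file bonds are used when
  present, otherwise bonds are inferred by a covalent-radius rule
  (d < r_i + r_j + 0.45 Å). Hydrogens are kept exactly as read — no
  implicit-H expansion — because donor typing lives on explicit polar
  hydrogens.
- Charge providers: `file` (pass through input charges), `gasteiger`
  (RDKit; falls back to an electronegativity-difference increment
  scheme for pseudo-atom molecules RDKit cannot sanitize), `zero`. The
  provider is recorded in model provenance.
- Grid linearization is x-fastest everywhere internally; cube and dx
  exporters reorder to each format's own convention (z fastest) and
  cube files are written in Bohr.
- Contour iso levels default to the 80th/20th percentiles of the
  nonzero StDev*Coeff distribution; the reference figures' levels are
  unstated, so these are declared defaults, not inferred ones.
- Translation invariance of the descriptor matrix holds to the last
  ulp (~1e-15), not bitwise: float addition does not commute with the
  lattice shift.

## Limitations

- The original 90-inhibitor structure set exists only as printed
  drawings; the packaged fixtures carry its observed/predicted activity
  table and summary statistics, so the internal-validation numbers of
  that study (q², per-combination statistics, field contributions,
  Y-randomization draws, AD status of individual compounds) cannot be
  recomputed here and are covered instead by the property-based tests
  above.
- No conformer generation, force-field minimization, tautomer or
  protonation handling: structures are used as given.
- Only minimum-sigma column pruning; no region focusing or variable
  selection.
- MOL2 support covers the MOLECULE/ATOM/BOND sections (enough for
  charges + geometry round-trips), not the full TRIPOS spec.
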