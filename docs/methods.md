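# Methods

## The matching model

A reference *marker panel* is one taxon's mapping from ten fixed slots
(A, B, X1, C, X2, D, X3, F, G, X4) to nominal monoisotopic peptide masses.
Slots are opaque labels for homologous tryptic collagen peptides; their
sequence identities are not modelled. A slot may be empty (marker not
determined) or carry two masses when the printed panel uses compressed slash
notation ("1832/48" = two tryptic variants, 1832 and 1848 Da). All masses lie
in the MALDI-TOF acquisition window 700–3,700 *m/z*; for singly charged MALDI
ions *m/z* is effectively the peptide mass, so "Da" and "*m/z* units" are used
interchangeably below.

Classification of a centroided peak list proceeds in four steps:

1. **Slot matching.** A slot is matched when some peak lies within
   ±`tolerance` of one of its masses. The nearest peak wins; each slot is
   matched at most once per panel; a peak may support slots in any number of
   panels. Matching is tolerance-based by construction — floating-point
   equality is never used.
2. **Qualification.** A panel qualifies when it has at least `min_matched`
   matched slots *and* at least `min_coverage` of its defined slots matched.
3. **Absence check** (optional, on by default). A qualifier P is discarded
   when another qualifier Q matches a superset of P's matched slots and the
   spectrum contains a peak within tolerance of some mass of Q but of no mass
   of P. "Explainable peaks" are computed over all panel masses, not only the
   recorded slot matches; this matters when two panels share one variant of a
   two-mass slot (warthog 1832/1848 vs red river hog 1816/1832: the 1848 peak
   is the discriminator) and when a diagnostic peak replaces another taxon's
   peak at a nearby mass (giraffe's 3003 with no 3033).
4. **Resolution.** Candidates are the surviving qualifiers with the maximum
   matched-slot count. The result is the lowest common ancestor (LCA) of the
   candidate taxa in the species→tribe→subfamily→family taxonomy. Ambiguity
   is reported, never broken: three reference species with identical panels
   resolve to their tribe, which is exactly how conserved bovid fingerprints
   behave.

An identification requires a non-empty candidate set; otherwise the status is
`no_id`.

### Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `tolerance` | 0.5 | Da | the packaged panels print nominal integer masses; ±0.5 Da brackets them against sub-dalton calibration error |
| `min_matched` | 4 | slots | the three highly conserved peptides (1427, 2131, 2883) plus one must never suffice alone |
| `min_coverage` | 0.5 | fraction | at least half a panel's defined slots must be present |
| `absence_check` | on | — | required to separate shared-variant panels (above); harmless elsewhere |
| `deamidation` | off | — | optionally also tries masses at +0.98/+1.97 Da (Asn/Gln → Asp/Glu in degraded collagen); off because the packaged panels were read as unshifted nominal masses |
| intensity filter | 0.01 | fraction of base peak | conservative noise floor; no threshold is prescribed by the expert-reading workflow the rule formalises, so it is a package decision exposed in config |

The thresholds formalise a manual interpretation step that was never
quantified by its practitioners; they are config keys so stricter or looser
judgement can be reproduced.

### Taxonomy decisions

The taxonomy is built from the panel file's family/subfamily/tribe columns,
with two printed-cell normalisations: the "Antelopinae" spelling variant is
folded into "Antilopinae", and the giraffe reference — printed under Bovidae,
contradicting both phylogeny and the study's own tree figure — is re-parented
to Giraffidae (the printed cell is preserved and the node flagged
`corrected`; panel files round-trip byte-identically). Taxa identified
archaeologically from previously published markers but without a packaged
panel (Equus, Leporidae, Aonyx, Hippotragus) receive taxonomy nodes only. The
suni / barbary sheep near-identity is left intact: suni's own full panel
resolves to species (its X4 slot is defined, barbary sheep's is not), while a
barbary sheep spectrum resolves only to family because suni matches every one
of its slots — the classifier surfaces the ambiguity instead of
special-casing it, and `panel_distance` (slots differing among those defined
in both) is 0 for the pair.

## The synthetic spectrum generator

The generator produces the statistical structure the classifier must survive,
not instrument physics:

- **Mass error**: i.i.d. Gaussian per emitted marker peak, SD `sigma`
  (default 0.15 Da, a typical external-calibration error for linear-mode
  MALDI-TOF at these masses). No drift model.
- **Dropout**: each marker mass is independently absent with probability
  `dropout` (default 0.1).
- **Noise**: `n_noise` uniform peaks over 700–3,700 *m/z* (default 5), with
  log-normal intensities well below the marker intensity distribution, the
  simplest model that exercises the intensity filter.
- **Total collagen failure**: with probability `fail_prob` the spectrum is
  noise-only. The default 0.49 emulates the packaged study's overall negative
  rate (41 of 84 samples). Heated specimens always fail when
  `heated_always_fail` is set (default), mirroring the observation that no
  visibly heat-damaged tool yielded a result; failed spectra carry a
  `collagen_failed` flag so experiments can separate failure from
  misclassification.

What the generator does *not* emulate: isotope envelopes, adducts,
deamidation-shifted masses, calibration drift, site-specific diagenesis, and
real intensity structure. Passing recovery tests therefore demonstrates that
the matching rule is correct and robust to the modelled degradations, not
that any particular real-world archive would classify at the same rates.

Under the realistic defaults (sigma 0.15, dropout 0.1, 5 noise peaks, 500
spectra per reference taxon — 15,000 classifications, a size chosen to keep
the Monte-Carlo standard error below half a percentage point) the resolved
clade contains the true taxon in ≥ 99 % of non-failed spectra; the residual
errors are spectra whose dropout pattern makes a sibling panel the unique
maximum. The no-identification rate converges on `fail_prob` as dropout and
noise vanish (binomially, so it is tested within three standard errors).

## The assemblage analytics

The packaged fixtures are verbatim tab-delimited transcriptions of the
study's printed tables (reference panels; faunal MNI per site; sampling
counts; per-site positive rates; per-specimen identifications), each with a
provenance comment line. Printed spellings are preserved (including the
Wozi/Wosi site-name variants, normalised on load via an alias table).
Analytic conventions:

- **Rounding**: printed-percentage reproductions use half-up rounding at the
  printed precision. The printed sampling table itself mixes conventions in
  two rows (its total prints 15.7 where the exact 15.7598 % rounds half-up to
  15.8); the package reports the half-up value and the tests document the
  bracket rather than widening a tolerance.
- **The specimen roster**: the printed identification table lists 83
  specimens but the sampling table says 84 were sampled; by default the
  loader pads each site's roster to the sampled count with explicit
  `placeholder` no-result records (one, at KwaGandaganda). This is also why
  computed KwaGandaganda positive rates differ from the printed positive-rate
  table (7/11 vs the printed 6/11) — the source's own tables disagree there,
  and validation treats that site as the single documented exception.
- **Period**: taken from the printed period column, never re-derived from the
  parsed date specifications (which are informational; "<", ">" and range
  forms are preserved as relations).
- **Heating**: a record is heated iff its observations note heating or
  calcination; discolouration alone does not qualify.
- **Faunal aggregation**: BOV I–IV size-class rows (morphologically
  unassignable fragments) never contribute to tribe totals. Presence-only
  'X' cells (from NISP-only reports) count as 0 by default, optionally 1;
  Caprini (domestic stock) and Bovini can be excluded from share
  denominators. All three choices are explicit parameters because the printed
  summary percentages do not state their convention — none of the tested
  conventions reproduces the printed "28 %" three-tribe share exactly, so
  that figure is treated as a narrative claim, not a reproduction target.
- **Tools-without-fauna**: a tool clade is flagged at a site when no faunal
  row belonging to it (tribe match, genus match, or family label) has an MNI
  count or presence mark there.
- **Selection test**: observed statistic is the total-variation distance
  between tool tribe shares (bovid tribes only, genus identifications rolled
  up) and faunal MNI tribe shares; the null draws the same number of
  identifications multinomially from the faunal shares; the p-value uses the
  add-one estimator (1 + exceedances)/(1 + permutations), which keeps null
  p-values approximately uniform and never exactly zero.

## Known limitations

- Nominal integer marker masses limit the meaningful tolerance range; the
  classifier is not suitable for high-accuracy reflectron data without
  re-entered panels.
- No probabilistic scoring: identifications are set-based (match counts and
  LCA), so near-threshold spectra flip between `no_id` and a call rather than
  degrading gracefully.
- The mzML reader is deliberately narrow: centroided spectra, 32/64-bit float
  arrays, zlib or no compression; profile data are rejected rather than
  centroided.
- The permutation test conditions on the identified-tool count and ignores
  per-site structure; it quantifies aggregate divergence, not which sites
  drive it.
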