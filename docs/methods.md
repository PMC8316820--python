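# Methods

## The identification problem

ZooMS assigns fragmentary bone to taxa by matching MALDI-ToF peptide mass
fingerprints of extracted type I collagen against a reference panel of
taxon-diagnostic tryptic peptides. Masses are nominal singly-protonated
([M+H]⁺) values in Da; reference tables print them as integers, so all
matching in this package is tolerance-based (default ±0.5 Da,
config-exposed) rather than exact. Several marker regions carry a
hydroxylation pair — two masses ~16 Da apart from variable proline
hydroxylation — which share one cell of the panel.

The packaged panel (`zoomsid/data/markers.tsv`) covers twelve taxa of the
eastern African Iron Age archaeofauna across twelve collagen marker
regions. Masses printed with "(?)" in reference tables are genuine
peptides seen in LC-MS/MS but unsuitable for species identification; they
load with `reliable=False` and can never serve as matched/missing
evidence, though they do make an observed peak *compatible* with the
taxon that carries them. One region label ("COL1a2 705-738", holding the
2843–2899 hydroxylation pairs) is an inferred transcription and is
flagged as such in the panel file, as are individual cells whose region
assignment was inferred; the functional content of the panel — each
taxon's reliable mass set, and in particular that sheep and goat differ
only at COL1α2 757–789 (3017(?)/3033 vs 3077/3093) — is what the
classifier consumes.

## Decision rules

Classification of a consensus peak list proceeds in order:

1. **Collagen gate.** The panel file declares the common collagen masses
   (present in ≥6 profiles: 1105, 1427, 1580, 1648, 2131, 2792, 2883,
   2899). Fewer than `min_common` (default 4) matches ⇒ the extraction
   failed ("failed"). The gate uses peak count, not intensity. It is
   deliberately conservative for taxa outside the bovid core — Canidae,
   Felidae and marine turtles share ≤2 of the common masses and cannot
   pass at the default threshold; `min_common` is config-exposed for
   panels where those taxa matter.
2. **Candidate survival.** A taxon is a candidate if ≥1 of its reliable
   marker masses is matched and no observed peak *excludes* it. A peak
   excludes a taxon when it matches panel masses (reliable or "(?)") of
   other taxa only. Absence of a marker never excludes — degraded
   collagen loses peptides — and peaks matching nothing in the panel
   (contaminants, unknown peptides) constrain nobody. Only peaks
   reproduced in **all** replicate spots may exclude: spot-specific
   chemistry (a contaminant in one spot, confirmed by a borderline noise
   maximum in another) must not veto an otherwise consistent profile,
   whereas genuine collagen peptides appear in every spot.
3. **Species call.** A single surviving candidate with *all* reliable,
   applicable markers matched. For hydroxylation pairs, `pair_mode="both"`
   (default) requires both reliable masses; `"any"` relaxes this — which
   of the two readings the original analysts used is not recorded, so it
   is exposed as a switch.
4. **Group fallback.** Several survivors that differ only at markers
   missing from the spectrum collapse to their lowest common taxonomic
   group. Sheep/goat with the 757–789 region absent is exactly this case
   and yields "caprine". A single surviving but incomplete candidate
   falls back to its parent group (the evidence points uniquely into that
   lineage without meeting the species bar), carrying the candidate in
   `competing_taxa`.
5. **Unknown.** Gate passed but no consistent candidate — including the
   pathological case of two internally complete profiles (a mixed spot),
   which is refused rather than guessed.

Taxa whose reference markers are predicted from genetic or proteomic
sequence data rather than measured LC-MS/MS (blue duiker, the turtles)
are flagged tentative; their calls render with a "cf." prefix.

## Synthetic spectra

The generator emulates what the pipeline assumes a collagen MALDI-ToF
acquisition looks like, on a uniform 0.05 Da grid over 800–3500 Da (fine
enough to resolve the ~1.002 Da isotope spacing):

- each retained marker mass contributes a Poisson isotope envelope
  (λ = m/1800, truncated at 4 isotopologues — adequate for 1–3.5 kDa
  tryptic peptides) convolved with a Gaussian whose σ grows linearly with
  m/z (`peak_sigma`, default 0.15 Da at m/z 2000);
- marker amplitudes are log-normal (σ = 0.3) so S/N gating is exercised;
  "(?)" masses are simulated ~30% weaker;
- an exponential chemical baseline (amplitude 0.2 of the max marker
  height at 800 Da, decay length 600 Da, offset 0.01), additive Gaussian
  noise (`noise_sd`, default 0.02 of max marker height), and uniform
  random contaminant peaks (default 8 per replicate);
- preservation: each specimen yields collagen with probability
  `preservation` (per site); failed specimens contain only
  baseline + noise + contaminants;
- degradation: each marker region drops with probability `dropout_prob`
  (default 0.05), both masses of a pair together. The three replicate
  spots of a specimen share its dropout draw (one extract) but have
  independent noise and contaminants (separate spots) — this is what
  makes the replicate-consensus and the all-replicates exclusion rule
  informative.

What the generator does **not** model: detector saturation, matrix
cluster chemistry, mass-dependent resolution changes beyond the linear σ
scaling, correlated (pink) noise, and real collagen sequence variation
within taxa. Passing tests therefore demonstrate that the pipeline
implements its rules correctly under a realistic spectral morphology, not
that it is robust to every instrument artefact of real archives.

The packaged example assemblage (`zoomsid.example_assemblage`) fixes the
study conditions of an eight-site island eastern Africa caprine survey:
394 sampled specimens, 318 with collagen (81%), goat dominating
successful identifications (259/318, 81%), few sheep (11/318, 3%),
per-site success from 6% (65 sampled) to 100%, and earliest caprine
occurrences in the 7th–9th centuries CE. Its tallies are inputs; every
percentage the package reports is recomputed from them at run time.

## Preprocessing

- **Baseline**: grey-scale morphological opening (rolling minimum then
  maximum) with a 100 Da window, after point-reflection padding so a
  sloping background is estimated without edge bias; exact for monotone
  backgrounds and blind to peaks much narrower than the window. Output
  clipped at zero.
- **Smoothing**: Savitzky–Golay, order 2, window 5 points.
- **Peak picking**: local maxima gated at S/N ≥ 3.5. Noise is a sliding
  robust scale (1.4826·MAD per ~100 Da block, interpolated), height is
  measured above the sliding robust median background, and the gate uses
  min(height, prominence) so noise bumps riding a larger peak's flank are
  rejected. Apexes are refined by a least-squares parabola over ±3
  samples; refined apexes closer than 0.3 Da collapse to the strongest.
- **Deisotoping**: ascending scan; a peak within 0.15 Da of
  base + k·1.00235 (k = 1..4) is absorbed if its height stays below a
  peptide-plausible multiple of the base (caps 2.2/2.0/1.3/0.7 — wide
  enough that heavy peptides whose +1 isotopologue exceeds the
  monoisotopic peak still collapse). Decisions depend only on surviving
  peaks, making the operation idempotent.
- **Replicate consensus**: peaks pooled across the three spots, clustered
  at 0.3 Da gaps; clusters kept if present in ≥2 replicates
  (`min_presence`, clamped to the number of spots supplied); m/z is the
  intensity-weighted mean, intensity the mean over spots where present.
  "Averaging" the triplicates at peak-list level (rather than summing
  traces) is chosen because the classifier consumes peak lists.

The external program originally used for these steps ran "with default
parameters" that are not recorded; the defaults above are this package's
own concrete, config-exposed choices.

## Reporting

Per-site summaries count sampled and successful specimens (percentages
rounded to integers, as such surveys print them; exact fractions retained
in JSON), tally calls, and code each successful call against the prior
morphological identification: **C** when ZooMS matches it (same node, or
a coarser call consistent with it — a "caprine" call on a
morphologically-identified goat confirms rather than contradicts), **I**
when ZooMS strictly refines it (proper taxonomic descent, or a taxon
inside a morphological size class's membership set), **F** for failed
extractions, **X** otherwise (true contradictions, and "unknown" calls,
which have no comparable taxon). Morphological size classes ("Bovid Size
1–2" etc.) are category nodes with explicit membership sets of panel
taxa, not clades.

Earliest dates are computed two ways: per site, the smallest interval
start among specimens called as the taxon or a descendant (ties by
smaller end, then radiocarbon over ceramic); across sites, the earliest
*securely dated* occurrence — radiocarbon-based associations preferred,
ranked by interval end (terminus ante quem) — because a wide
low-resolution bracket can start centuries before the earliest secure
occurrence. Century labels are normalized to year intervals (e.g. "7th
century CE" → 601–700) in the packaged data.

## Problem sizes and numerical choices

The test suite and acceptance script run the recovery experiments at 200
specimens per taxon for the four bovid taxa on which the survey's
discrimination problem turns (goat, sheep, cattle, duiker), 60 noiseless
forced-dropout goats for the caprine-fallback check, and one full
394-specimen simulated survey; the classifier-vs-oracle equivalence check
enumerates all 4096 subsets of a 12-mass core universe plus 3000 seeded
random ≤10-mass subsets of the 6-taxon sub-panel universe. All
randomness flows from explicit seeds; fixed seed ⇒ byte-identical
outputs, including written files.

Known limitations: the collagen gate under-serves non-bovid taxa (above);
a contaminant coinciding with a shared panel mass in all three spots
would wrongly support a taxon (probability ≲10⁻⁴ per specimen at default
settings); strict presence/absence logic carries no confidence measure —
probabilistic scoring is explicitly out of scope.
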