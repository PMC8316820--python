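# zoomsid

Zooarchaeology by Mass Spectrometry (ZooMS) identifies fragmentary
archaeological bone by the masses of taxon-diagnostic tryptic peptides from
type I collagen (COL1α1/COL1α2), measured by MALDI-ToF. On eastern Africa's
islands the method matters because sheep (*Ovis aries*) and goat (*Capra
hircus*) bones are rarely separable morphologically, yet the two species
imply different herding economies and ecological impacts. `zoomsid`
implements the full identification workflow used in Iron Age caprine
surveys of the Zanzibar, Mafia and Comoros archipelagos, for
zooarchaeologists and methods developers who want a testable, end-to-end
reference pipeline:

- a curated collagen **peptide-marker panel** (taxa × marker regions,
  nominal [M+H]⁺ masses, hydroxylation pairs, "(?)"-flagged masses that are
  real peptides but unsuitable for identification) plus the taxonomy used
  for group-level calls and morphological size classes;
- a seeded **synthetic-spectrum generator** (isotope envelopes, Gaussian
  peak shapes, exponential baseline, noise, contaminants, calibration
  drift, preservation-dependent collagen failure, degradation-driven
  marker dropout) so every stage is testable without deposited raw data;
- **preprocessing**: baseline correction, Savitzky–Golay smoothing, peak
  picking at signal-to-noise ≥ 3.5, deisotoping to monoisotopic peaks, and
  a consensus merge of the triplicate MALDI spots per specimen;
- a **hierarchical classifier** implementing the field's decision rules:
  a species call requires *every* diagnostic reliable marker to be
  present; sheep/goat spectra missing the COL1α2 757–789 marker (sheep
  3033, goat 3077/3093) demote to "caprine"; wild bovids sharing markers
  collapse to their lowest common taxonomic group; spectra with collagen
  but no consistent profile are "unknown"; spectra failing the
  common-collagen-peptide gate are "failed";
- **assemblage reporting**: per-site sampled N and collagen-success
  percentages, counts per taxon call, C/I/F/X codes against prior
  morphological identifications, and earliest associated date ranges per
  taxon.

## Worked example

The packaged demo simulates two small sites and runs the whole pipeline:

```
$ python -c "from importlib import resources; open('demo.yaml','w').write(
    resources.files('zoomsid.data').joinpath('demo.yaml').read_text())"
$ zoomsid run --config demo.yaml
11/14 specimens successful (79%); outputs in zoomsid_demo_out
```

`zoomsid_demo_out/site_summary.csv` then contains (actual output):

```
site_id,n_sampled,n_success,pct_success,...,cif_C,cif_I,cif_F,cif_X,earliest_Capra hircus,...
DEMO-A,8,8,100,...,5,3,0,0,655-710 CE (radiocarbon),...
DEMO-B,6,3,50,...,2,1,3,0,701-900 CE (ceramic),...
```

Reading: all 8 DEMO-A specimens yielded collagen (100%); at DEMO-B, half
the extractions failed (3 F codes — the site was configured with poor
preservation). Specimen-level calls are in `classifications.csv`; e.g.
`DEMO-A-0001,caprine,subfamily,...` is a goat spectrum whose COL1α2
484–498 marker dropped out, so the species bar is not met and the call
falls back to the containing group, listing *Capra hircus* under
`competing_taxa`. The `earliest_*` columns give each site's earliest date
range associated with a given taxon call (radiocarbon preferred over
ceramic at ties).

The same stages are importable directly:

```python
import zoomsid as z
panel, tree = z.load_panel(), z.load_taxonomy()
peaks = z.process_specimen(replicate_spectra)   # three RawSpectrum objects
result = z.classify(peaks, panel, tree)
print(result.display_call, result.rank, sorted(result.missing_markers))
```

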