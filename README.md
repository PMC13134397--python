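# glycopop

Population-level analysis of glycoprotein glycoforms.

A glycoprotein is never a single molecule but a *population* of
glycoforms: variants sharing an amino-acid backbone that differ in the
glycan attached at each site. `glycopop` analyzes glycopeptide mass
spectrometry data at the population level rather than one glycoform at
a time, combining three layers:

1. **Spectral networking + network walk.** Glycopeptide MS/MS scans
   (recognized by the HexNAc oxonium ion at m/z 204.09) are clustered
   into consensus nodes and connected when their spectral cosine
   reaches 0.7 with ≥ 6 matched fragments. Database-search
   identifications seed the network, and annotations propagate along
   edges whose precursor mass difference matches a combination of at
   most two monosaccharide additions/removals within 0.1 Da — e.g. a
   +15.995 Da shift is one fucose (−146.058) swapped for one hexose
   (+162.053). Propagation iterates to a fixed point.
2. **GlycoPOP-MS feature quantification.** Instead of deconvoluting
   individual precursors, very wide DIA isolation windows (600 Da)
   co-fragment entire co-eluting glycoform populations. Fragment
   transitions from all precursors are collapsed into *feature
   superclasses* (fucosylation, galactosylation, sialylation,
   high-mannose); only feature-specific transitions are quantified,
   normalized to the Y1 ion (peptide + HexNAc).
3. **Biodiversity statistics.** Site-specific glycoform abundance
   distributions are treated as ecological communities: richness *S*,
   Shannon *H = −Σ pᵢ ln pᵢ*, inverse Simpson *D₂ = 1/Σ pᵢ²*, evenness
   (Pielou *J = H/ln S* and Hill ratio *D₂/S*), Fisher's log-series α
   (solving *S = α ln(1 + N/α)*), and Rényi profiles
   *H_a = ln(Σ pᵢᵃ)/(1−a)* over *a ∈ {0, 0.25, …, 64, ∞}*.

A fully ground-truthed synthetic data generator (log-series-skewed
glycoform populations on IgG Fc tryptic backbones, oxonium/Y-ladder
MS/MS spectra, DDA and wide-window DIA runs, an endoglycosidase
truncation time course) makes every stage testable without external
data.

Intended users: glycoproteomics researchers who want a scriptable,
locally runnable version of this workflow — reading MGF/mzML, PSM
tables and abundance CSVs, writing Cytoscape/Skyline-compatible
exports.

## Worked example

```python
import numpy as np
import glycopop as gp

# composition algebra
g = gp.parse_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)")
print(round(gp.composition_mass(g), 4))                      # 2059.7349
print(round(gp.GlycopeptideIon("EEQYNSTYR", g, 2).mz(), 4))  # 1625.1271

# simulate an IgG1-like population and run networking + the walk
cfg = gp.SimulationConfig(seed=7)
panel = gp.sample_population(cfg, condition="ivig")
run, truth = gp.simulate_dda_run(panel, cfg)
spectra = [gp.preprocess_peaks(s) for s in gp.oxonium_filter(run.ms2())]
net = gp.build_network(gp.cluster_spectra(spectra))
# seed 30% of glycoforms from the simulation truth, then propagate
by_g = {}
for sid, key in sorted(truth.scan_truth.items()):
    by_g.setdefault(key, []).append(sid)
keys = sorted(by_g)
rng = np.random.default_rng(7)
chosen = [keys[i] for i in rng.choice(len(keys), 9, replace=False)]
psms = [gp.SeedAnnotation(by_g[k][0], k[0], gp.parse_composition(k[1]), 300.0)
        for k in sorted(chosen)]
report = gp.walk(net, psms)
print(report.n_seeded, report.n_propagated)                  # 9 21

# diversity of the planted population
profile = gp.diversity_profile(panel["proportion"].to_numpy() * 100, "ivig-like")
print(profile.richness, round(profile.inverse_simpson, 2),
      round(profile.fisher_alpha, 2))                        # 30 5.56 5.82
```

The network walk annotated all 21 unseeded nodes from 9 seeds by
decomposing edge mass differences into residue changes. The planted
population has 30 glycoforms but an inverse Simpson diversity of only
5.6 — a handful of dominant glycoforms and a long rare tail, the
log-series skew typical of site-specific glycosylation.

A CLI mirrors the library (`glycopop simulate`, `filter-scans`,
`network`, `walk`, `diversity`, `run-all`); `glycopop run-all --seed 7
--out out/` runs every stage on a synthetic population and writes a
manifest with checksums.

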