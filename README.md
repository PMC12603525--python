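# synmap

Quantification of single synapses in multi-channel fluorescence
micrographs: puncta detection, per-region density and intensity tables,
object-based colocalization, and derived marker-fraction reports — with a
synthetic micrograph generator that makes every stage verifiable against
known ground truth.

The package targets the kind of synaptome-mapping study in which brain
tissue sections are immunolabelled for panels of presynaptic (SV2A, SYP,
SYN, VGLUT1, VGAT) and postsynaptic (PSD95, GPHN) markers, imaged at
high resolution (68 nm pixels, 12-bit data in 16-bit TIFF tiles of
942 × 920 px mosaicked without overlap), and quantified as
diffraction-limited puncta. It is aimed at imaging scientists who need a
tested, scriptable reimplementation of that pipeline, and at
methodologists who want to study its error characteristics on simulated
data.

## What it computes

- **Detection.** A scale-normalised Laplacian-of-Gaussian detector with
  the three per-marker knobs practitioners tune per antibody: punctum
  radius *r* (filter scale σ = r/√2), a quality threshold on the LoG
  response (absolute, or "auto" = the mean quality of all candidate
  maxima), and an intensity threshold on the disc-mean intensity.
  Non-maximum suppression at one radius separation, optional subpixel
  refinement, deterministic output.
- **Quantification.** Puncta density per 100 µm² of ROI area
  (100·N/A), mean punctum intensity (a.u.), aggregated across biological
  replicates as mean ± SEM (sd/√n, n = subjects).
- **Colocalization.** One-to-one matching of two marker channels by
  centroid distance (maximum cardinality, minimum total distance;
  ≤ 300 nm default for presynaptic pairs, ≤ 500 nm for presynaptic–
  postsynaptic *juxtaposition*), reported as the percentage of marker-B
  puncta containing a reference (e.g. SV2A-positive) punctum, with an
  analytic spatial-Poisson chance level
  100·(1 − exp(−(ρ_A/100)·π·d²)) for null calibration.
- **Reports.** Marker-fraction tables (reference density as a percent of
  a summed marker panel, e.g. %SV2A = 100·ρ_SV2A/(ρ_VGLUT1 + ρ_VGAT)) and
  row-normalised heatmaps ordered by average-linkage hierarchical
  clustering.
- **Simulation.** Multi-channel fields of isotropic-Gaussian puncta
  (Poisson counts at configurable density, log-normal size jitter,
  truncated-normal amplitudes) with controlled colocalized/juxtaposed
  fractions between channels, Poisson shot noise and Gaussian read
  noise, plus full ground truth for recall/precision/RMSE scoring.

Bundled reference tables (`synmap.refdata`) carry the published
marker × region density, intensity and colocalization summaries for
nine mouse brain regions and the six layers of human temporal cortex
that calibrate the simulator and feed the worked examples.

## Worked example

Reproduce the SV2A-fraction table from the bundled mouse densities, then
simulate a two-channel field and recover its ground truth:

```python
from synmap import (SynthConfig, ChannelConfig, PairConfig, generate_field,
                    DetectionParams, detect_puncta, evaluate_detection,
                    match_puncta, percent_with_reference, puncta_density,
                    build_fraction_table, round_fraction_table, refdata)

table = round_fraction_table(
    build_fraction_table(refdata.mouse_density_mean(), "SV2A", ["VGLUT1", "VGAT"])
)
print(table.to_string())

cfg = SynthConfig(
    field_size_um=(100.0, 100.0),
    channels=[ChannelConfig("SV2A", density_per_100um2=19, amplitude_mean=386, amplitude_sd=58),
              ChannelConfig("VGLUT1", density_per_100um2=16, amplitude_mean=236, amplitude_sd=35)],
    pairs=[PairConfig("SV2A", "VGLUT1", fraction=0.67, mode="colocalized")],
    seed=1,
)
images, truth = generate_field(cfg)
ps = {}
for img, thr in zip(images, (46.0, 28.0)):
    ps[img.channel_label] = detect_puncta(
        img, DetectionParams(quality_threshold=thr, exclude_border=False))
for name, p in ps.items():
    score = evaluate_detection(p.positions, truth.positions(name), 0.3)
    print(f"{name}: {len(p)} puncta, density {puncta_density(p):.1f}/100 um^2, "
          f"recall {score.recall:.3f}, precision {score.precision:.3f}")
res = percent_with_reference(
    match_puncta(ps["SV2A"], ps["VGLUT1"], mode="colocalized"), ps["VGLUT1"])
print(f"VGLUT1 puncta containing SV2A: {res.percent_b_with_a:.1f}% "
      f"({res.n_matched}/{res.n_b})")
```

Output:

```
               CA1sr  CA2sr  CA3sr  DGpo  SMSL2/3  SMSL5  ENTIL4/5  STRcp  THpo  Mean
marker
SV2A              19     18     18    16       18     17        18     16    15    17
VGLUT1 + VGAT     29     29     28    21       28     27        30     24    18    26
% SV2A            66     62     64    76       64     63        60     67    83    65

SV2A: 1867 puncta, density 18.7/100 um^2, recall 0.982, precision 1.000
VGLUT1: 1586 puncta, density 15.9/100 um^2, recall 0.985, precision 1.000
VGLUT1 puncta containing SV2A: 66.6% (1057/1586)
```

The fraction row reads: SV2A puncta density is 60–83 % of the combined
excitatory + inhibitory presynaptic marker density depending on region —
evidence that SV2A is expressed in a subset of synapses rather than
universally. In the simulation, the detector recovers the configured
densities (19 and 16 per 100 µm²) and the observed colocalization
(66.6 %) sits at the configured paired fraction (67 %) once chance
overlap is accounted for.

A CLI mirrors the library:
`synmap simulate | stitch | detect | quantify | coloc | report`
(see `synmap --help`).

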