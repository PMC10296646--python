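# mifcal

Cross-microscope calibration and standardization for multispectral,
multiplex immunofluorescence (mIF) imaging.

## The problem

High-throughput mIF studies scan whole slides as tiled "high-power field"
(HPF) image stacks — here K = 43 narrowband layers of unsigned 16-bit
counts, acquired through 7 static broadband filter cubes. When the same
tissue is scanned on different multispectral microscopes, differences in
illumination intensity and spectral sensitivity (dominated by each
instrument's broadband filter cubes) shift both the overall brightness and
the per-layer shape of the measured flux spectra. Those shifts propagate
into spectrally unmixed marker-expression measurements, so data from
different instruments cannot be pooled, compared, or fed to a common
analysis pipeline without correction.

`mifcal` implements a sequential multiplicative correction model for this
problem, plus everything around it: tile I/O, tissue masking, flux-spectra
reduction, residual diagnostics, a fit/test bootstrap of the microscope
factors, standardization of raw images to a reference microscope, and a
non-negative least-squares spectral unmixer for evaluating the effect on
marker measurements. Because real multi-microscope scan sets are large and
rarely shareable, the package ships a first-class synthetic-data generator
with known ground truth; every pipeline stage is validated against it.

## The model

For sample n, microscope m, scan repeat r, and image layer k, the
exposure-normalized, tissue-masked, HPF-weighted, grand-mean-normalized
average flux spectra `X_{nmrk}` (grand mean 1) are corrected in sequence:

```
a_{nmr} = mean_k X / grand_mean          per-scan amplitudes
B_n = mean_{m,r} a,  C_m = mean_{n,r} a  sample / microscope amplitudes
x = X / (B_n C_m)
b_nk = mean_{m,r} x / mean_{n,m,r} x     sample spectral profile (per k)
y = x / b_nk
w_mk = mean_{n,r} y / mean_{n,m,r} y     microscope spectral profile (per k)
z = y / w_mk
```

All factors carry mean-one gauge conventions, and `w_mk` decomposes into
illumination x broadband-group x narrowband parts,
`w_mk = w_ill,m * w_BB,mk * w_NB,mk` (exact reconstruction). Residual
variation is summarized by the per-layer standard deviation across all
(n, m, r) and by the layer-projected covariance matrix centered on each
microscope's own mean. Generalization is measured by refitting the
microscope factors on every C(N, N′) subset of samples and applying them to
the held-out samples. The three corrections are also available as sklearn
transformers (`AmplitudeCorrection`, `TissueProfileCorrection`,
`MicroscopeProfileCorrection`) that compose in an `sklearn.pipeline.Pipeline`.

## Worked example

```python
from mifcal import (SimulationConfig, TruthModel, simulate_dataset,
                    run_full_calibration)

config = SimulationConfig()            # 8 samples x 3 microscopes x 2 scans,
truth = TruthModel.random(config, seed=1)   # 12 layers, 64x64 tiles
dataset = simulate_dataset(config, truth)
report = run_full_calibration(dataset)

for stage in ("X", "x", "y", "z"):
    print(stage, round(report.stage_std[stage].mean_percent, 2))
s = report.bootstrap_summary
print("fit", round(100 * s.mean_fit_std, 2), "test", round(100 * s.mean_test_std, 2))
```

prints

```
X 20.0
x 10.52
y 6.94
z 0.48
fit 0.48 test 0.49
```

Reading: the simulated instruments and samples start 20.0% apart on average
over layers; dividing out the sample and microscope amplitudes leaves
10.5%; removing each slide's spectral profile leaves 6.9%; removing each
microscope's spectral profile leaves 0.48%, the injected noise floor. The
56-subset bootstrap shows the microscope factors generalize: residuals on
held-out samples (0.49%) match the samples used for fitting (0.48%).

The same pipeline runs from the shell on an on-disk dataset (multi-page
TIFF tiles + YAML manifest):

```sh
mifcal simulate data/ --seed 1
mifcal run-all data/manifest.yaml --outdir run/
```

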