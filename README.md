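# smstoich — single-molecule TIRF brightness stoichiometry

`smstoich` quantifies the subunit composition of membrane protein oligomers
from single-molecule TIRF movies. It was built for brightness-based
stoichiometry of pore-forming proteins such as gasdermin D (GSDMD)
reconstituted in supported lipid bilayers or retained in native plasma-membrane
sheets, where each assembly appears as a diffraction-limited spot whose
fluorescence intensity counts its mEGFP-tagged subunits. The package covers
the complete chain:

- **`smstoich.synth`** — synthetic TIRF movie generation with ground truth
  (pixel-integrated Gaussian PSFs, Poisson–Gamma EMCCD noise, binomial
  fluorophore labeling, Brownian mobility), so every downstream stage is
  testable without raw data;
- **`smstoich.detect`** — difference-of-Gaussians spot detection, 2-D
  Gaussian photometry with local-background subtraction, and the
  overlap/multi-peak/PSF-width quality filters;
- **`smstoich.stoich`** — monomer brightness calibration, kernel-density
  estimation of the brightness distribution, the calibrated Gaussian-mixture
  fit, the binomial partial-labeling correction, and particle densities;
- **`smstoich.track`** — frame-to-frame linking and immobile/mobile
  classification;
- **`smstoich.leakage`** — the calcein-release liposome permeabilization
  statistic.

## The model

A spot containing `k` fluorescent subunits has brightness distributed
approximately as `N(k·μ₁, √k·σ₁)`, where `(μ₁, σ₁)` are the mean and standard
deviation of the single-fluorophore brightness measured in a calibration
experiment (surface-captured monomeric mEGFP). The kernel probability
density `p(B)` of all accepted spot brightnesses is decomposed as

    p(B) ≈ Σₙ wₙ · N(B; n·μ₁, √n·σ₁),   wₙ ≥ 0,  Σ wₙ = 1,  n = 1…30,

by nonnegative least squares; the weight `wₙ` is the occurrence fraction of
the `n`-labeled species. Because each genetically encoded fluorophore is
fluorescent only with probability `p` (≈ 0.70 for mEGFP), the label counts
`k` underestimate true subunit counts `n`; the observed fractions are related
to the true ones through the binomial mixing matrix

    obs(k) ∝ Σₙ f(n) · C(n,k) pᵏ (1−p)ⁿ⁻ᵏ,   k ≥ 1,

which `smstoich` inverts by constrained least squares to report
labeling-corrected fractions. Particle density is the accepted spot count
normalized to the field-of-view (or cell-mask) area; mobility percentages
follow the minimum-immobile-time (10 frames) / minimum-mobile-time (5
frames) track classification; percent calcein release is
`100·(F_sample − F_onlyLUVs)/(F_Triton − F_onlyLUVs)` with per-well Triton
maxima.

The inference steps are scikit-learn-style estimators
(`MonomerCalibrator`, `StoichiometryModel`, `MobilityClassifier`) with
`fit`/`predict`, `get_params`, and trailing-underscore fitted attributes; the
module-level functions are thin wrappers around them.

## Worked example

Simulate a 50/50 dimer/trimer bilayer field at 70% labeling with the default
EMCCD model (100 nm pixels, EM gain 65.4, offset 170) and analyse it:

```bash
cat > example.yaml <<'YAML'
seed: 7
simulate.field_width_nm: 32000.0
simulate.field_height_nm: 32000.0
simulate.n_emitters: 300
simulate.n_frames: 12
simulate.min_separation_nm: 1000.0
detection.n_frames_analyze: 4
stoich.mu1: 250.0
stoich.sigma1: 70.0
YAML
smstoich simulate --config example.yaml --out sim
smstoich run --movie sim/movie.tif --config example.yaml --out results
```

which prints

```
wrote sim/movie.tif (12 frames, 300 emitters)
smstoich INFO stage=load frames=12 shape=(320, 320)
smstoich INFO stage=detect frames_analyzed=4 detected=1105 accepted=1063 rejected=42
smstoich INFO stage=density area_um2=1024.0 density_um2=0.2595
smstoich INFO stage=stoich n_particles=1063 residual=8.89e-05
accepted 1063 particles, density 0.2595 /um^2, corrected fractions {2: 0.4328, 3: 0.5605, 6: 0.0067}
```

The field truly contains only dimers and trimers at ~0.3 particles/µm²; after
detection, photometry, the mixture fit and the labeling correction the
pipeline reports ≈ 43% dimers and ≈ 56% trimers from 1063 accepted spots —
the residual deviation from 50/50 reflects the finite particle count.
`results/` holds the localization table, the brightness Pdf, the result JSON
and the fully resolved configuration. In Python the same analysis is

```python
from smstoich import StoichiometryModel
model = StoichiometryModel(mu1=250.0, sigma1=70.0, labeling_p=0.7).fit(brightness)
model.corrected_fractions_   # {1: ..., 2: ..., 3: ..., ...}
```

The CLI also provides `detect`, `track`, `stoich` and `leakage` subcommands;
all honour `--seed`, `--config` and `--out`.

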