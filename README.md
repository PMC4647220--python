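# gabagamma

Multimodal MEG/PET analysis pipeline linking the properties of visually
induced gamma oscillations in primary visual cortex (V1) to GABA_A receptor
density — rebuilt as a fully synthetic, parameter-recovery-verifiable
package.

## The scientific problem

Gamma-band oscillations (~40–100 Hz) are thought to be generated by
pyramidal–interneuron loops whose timing is governed by GABAergic
inhibition.  One multimodal strategy for testing this in humans combines

* **MEG**: visually induced gamma responses in V1, localized with an
  event-related DICS beamformer (Morlet-wavelet cross-spectral densities,
  spherical head model), and summarized per subject by the gamma **peak
  frequency**, **peak timing** and **peak amplitude** of the
  baseline-normalized V1 response; and
* **Flumazenil PET**: GABA_A (benzodiazepine-site) receptor density
  **B′max**, estimated voxelwise from a single partial-saturation injection
  via the Scatchard relation `B/F = (B′max − B)/K_d`, with the free-ligand
  concentration `F` taken from the pons and the bound range from the
  occipital cortex, then aggregated as the **total density over the unique
  set of V1 PET voxels**.

Across subjects, the receptor density should correlate **positively with
gamma peak frequency** and **negatively with gamma amplitude**.  The
correlation analysis uses Spearman's ρ, Pearson's r (two-sided p, df = n−2),
the default **JZS correlation Bayes factor**

    BF10 = ∫ (1+g)^((n−2)/2) (1+(1−r²)g)^(−(n−1)/2)
             × √(n/2)/Γ(½) g^(−3/2) e^(−n/(2g)) dg,

leave-2-out bootstrap 95% confidence limits, confound regression (V1
surface area, gray-matter density) and random-voxel specificity nulls.

Because no raw MEG/PET data of this kind are public, the package ships a
**synthetic cohort generator** whose latent parameters (per-subject gamma
peak frequency/amplitude/latency, voxelwise B′max fields, confounds) are
known exactly and coupled with configurable strength — so every stage of
the pipeline is testable by parameter recovery rather than by eyeballing.

## Layout

    src/gabagamma/         library: synthetic_cohort, meg_source_power,
                           oscillation_features, pet_parametric,
                           gaba_gamma_stats, pipeline, geometry, io, cli
    analysis/              numbered drivers: 01 simulate, 02 beamform,
                           03 B'max, 04 correlate, 05 recovery study
    scripts/acceptance.py  recomputes the headline Bayes factors
    tests/                 pytest suite incl. parameter-recovery checks

## Worked example

```python
import numpy as np
from gabagamma.geometry import CohortGeometry
from gabagamma.synthetic_cohort import CohortConfig
from gabagamma.pipeline import AnalysisScale, run_cohort
from gabagamma.gaba_gamma_stats import PairedSample, spearman, \
    pearson_with_p, jzs_correlation_bf

geom = CohortGeometry.reduced()
config = CohortConfig.calibrated(geom, seed=1)   # truth-level rho ~ 0.75
df = run_cohort(config, geom, AnalysisScale.reduced())
s = PairedSample(df.total_v1_bmax, df.gamma_peak_freq_hz)
rho, p = spearman(s)
r, rp = pearson_with_p(s)
print(f"rho={rho:.3f} p={p:.4f}  r={r:.3f}  BF10={jzs_correlation_bf(r, s.n):.2f}")
```

prints (10 subjects, seeded):

    rho=0.707 p=0.0221  r=0.714  BF10=3.48

i.e. the pipeline recovers a positive density–frequency correlation close
to the injected truth-level ρ = 0.758, significant at p < 0.05, with a
Bayes factor favoring a correlation.  The same frame's
`df.gamma_peak_amp` column gives the recovered negative amplitude
correlation (ρ = −0.661, identical ranks to the truth for this seed).

The command-line interface mirrors the drivers:

    gabagamma simulate --out results/sim --seed 42
    gabagamma pet --dynamic results/sim/pet_S01.nii.gz \
        --pons results/sim/mask_pons.nii.gz \
        --occ results/sim/mask_occipital.nii.gz \
        --v1 results/sim/mask_v1.nii.gz --out bmax_S01.nii.gz
    gabagamma correlate --features results/features.csv \
        --density results/density.csv --out results/

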