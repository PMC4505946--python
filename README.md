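# vtmorph

Morpho-acoustic analysis of the lower vocal tract in singing.

Male classical singers produce a prominent spectral energy cluster near
3 kHz — the singer's formant cluster — that is thought to arise from a
narrow epilaryngeal tube opening into a widened hypopharynx: when the
outlet-to-pharynx area ratio falls below about 1:6, the epilarynx resonance
decouples from the rest of the tract. `vtmorph` implements the full
quantitative chain needed to study this hypothesis with volumetric imaging
and audio of sustained vowels:

- **geometry** — from a segmented 3D airway volume (NIfTI) to a mid-lumen
  centerline, cross-sections normal to it at 0.3255 mm spacing, and the
  area function A(x) of the tract;
- **morphometry** — the five lower-VT measures relative to the
  epilarynx-exit reference plane (the slice just below the uppermost
  complete posterior arytenoid closure): endolaryngeal area **ELA** and
  volume **ELV**, hypopharyngeal area **HPA** (30 slices = 9.765 mm above
  the reference) and volume **HPV**, and laryngeal height **LH** from
  cervical-spine helplines; relative measures
  `pc = singing/speech x 100`, the ratios ELA/HPA and ELV/HPV, and the
  analytic circular-area error estimate;
- **acoustics** — a native 1D transmission-line (chain-matrix) model of
  the tract transfer function with lossy telegraphist equations,
  piston-in-baffle lip radiation and finite glottal resistance; hybrid
  area functions splicing one mode's lower VT onto the other's upper VT at
  the vallecula; formant extraction;
- **spectrum** — long-term average spectra (250 Hz bands to 5.5 kHz),
  equivalent-level loudness compensation, and the Hammarberg index
  `HI = max level below 2 kHz - max level in 2-5 kHz`, with
  `delta_HI = HI_speech - HI_singing`;
- **stats** — two-way repeated-measures ANOVA (mode x vowel, within
  subjects, Greenhouse-Geisser corrected), OLS regressions with signed r,
  and cohort summary tables;
- **synthetic** — a ground-truthed generator of airway volumes, landmark
  sets, cohort tables and audio emulating the study design (13 subjects,
  5 vowels, 2 phonation modes, 8 mm larynx lowering, +21.9 % / +16.8 %
  hypopharyngeal area/volume widening in singing), so the entire pipeline
  is testable without any imaging data.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

Generate a synthetic speech/singing tract pair, splice a hybrid with the
singing lower vocal tract, and compare 4th formants:

```python
import numpy as np
from vtmorph import synthetic as sv, acoustics as ac

speech  = sv.make_area_profile(sv.SyntheticVTParams(mode="speech_like"))
singing = sv.make_area_profile(sv.SyntheticVTParams(mode="singing"))
hybrid  = ac.splice_hybrid(singing, speech)   # singing lower VT + speech upper VT

cfg, grid = ac.AcousticConfig(), np.arange(0, 5500, 5.0)
f_speech = ac.find_formants(ac.transfer_function(speech, cfg, grid), 4)
f_hybrid = ac.find_formants(ac.transfer_function(hybrid, cfg, grid), 4)
print("F4 all-speech:", f_speech[3][0], "Hz")
print("F4 hybrid:    ", f_hybrid[3][0], "Hz")
```

prints

```
F4 all-speech: 3555.0 Hz
F4 hybrid:     3405.0 Hz
```

— attaching the singing lower vocal tract (wider hypopharynx, larynx
lowered by 8 mm) lowers the 4th formant by 150 Hz, the direction expected
if the lower VT shapes the singer's formant region. A cohort-level check:

```python
from vtmorph import stats as st
cohort = sv.make_cohort(seed=1)            # 13 subjects x 5 vowels x 2 modes
s = st.summarize_cohort(cohort.table)
print(round(s["delta_pc"].loc["all", ("delta_pc_HPA", "mean")], 1))  # 21.9
print(round(s["delta_lh"].loc["all", "mean"], 1))                    # 8.0
print(s["ratios"].loc[:, "area_ratio_mean"].round(2).to_dict())
# {'speech_like': 0.29, 'singing': 0.27}
```

The measured table recovers the injected hypopharyngeal widening (+21.9 %)
and larynx lowering (8 mm), and the larynx-to-pharynx area ratio drops in
singing — the morphometric signature of a tract configured for a singer's
formant cluster.

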