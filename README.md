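# hybridflair

Hybrid synthetic FLAIR reconstruction: physics-based FLAIR synthesis from
quantitative MRI maps, repaired in k-space with an ultra-undersampled
conventional FLAIR acquisition.

## The problem

Synthetic MRI computes contrast-weighted images offline from quantitative
T1/T2/proton-density maps via an analytic signal model. For FLAIR
(fluid-attenuated inversion recovery), the purely physics-based rendering
is known to misrepresent lesions: un-modeled effects — magnetization
transfer, partial volume, diffusion, susceptibility — make real lesions
hyperintense on an acquired TSE FLAIR while the synthetic one renders them
iso- to hypointense. This package implements a hybrid remedy: acquire a
*very* short conventional FLAIR covering only the central 12.5% of
phase-encode lines (acceleration R = 8, a keyhole), and splice that
contrast-carrying band into the synthetic image's k-space.

## The method

Physics-based synthesis evaluates the inversion-recovery spin-echo signal
voxelwise:

    S_P = PD · (1 − 2e^(−TI/T1) + e^(−TR/T1)) / (1 + e^(−TR/T1) cos θ) · e^(−TE/T2)

The hybrid image is

    H = F⁻¹( F(S_C,R) · w(y) + N · F(S_P) · (1 − w(y)) )

where `S_C,R` is the registered, brain-masked, undersampled conventional
image, `w(y)` a Tukey (cosine-tapered, ratio r = 0.25) window supported on
the acquired keyhole band, and `N = RMS(|F(S_C,R)|·w) / RMS(|F(S_P)|·w)`
an intensity normalization computed on the window support. The skull
region is reinserted from `S_P` afterwards. The taper trades off the
truncation ringing of a hard (boxcar) keyhole edge against the blurring of
a full Hann window. The keyhole FLAIR adds 40 s to a 300 s quantitative
scan — a 13% protocol cost.

Lesion conspicuity is scored by lesion-to-GM/WM signal ratios and CNRs
(noise = median of the lesion/GM/WM intensity standard deviations), SSIM
against the conventional image, and a paired exact Wilcoxon signed-rank
test across subjects.

No patient data ships with the package; a seeded digital brain phantom
(nested ellipsoidal scalp/skull/GM/WM/CSF structures, a WM lesion, a
lesion-hyperintensity mismatch factor λ, TSE magnetization-transfer-like
tissue attenuation, complex Gaussian k-space noise, optional rigid
misalignment, prospective or retrospective keyhole acquisition) provides a
fully reproducible test bed.

## Worked example

```python
import json
import hybridflair as hf

cfg = hf.RunConfig(shape=(4, 224, 224), seed=7)   # λ=1.8, R=8, r=0.25
res = hf.run_pipeline(cfg)
print(json.dumps(res.metrics, indent=2, sort_keys=True))
```

prints (abridged):

```
"physics":      {"lesion_wm_ratio": 1.86, "cnr_wm": 14.9, "cnr_gm": 2.7,  "ssim_vs_conventional": 0.9369}
"hybrid":       {"lesion_wm_ratio": 3.43, "cnr_wm": 31.4, "cnr_gm": 20.9, "ssim_vs_conventional": 0.9378}
"conventional": {"lesion_wm_ratio": 3.81, "cnr_wm": 44.7, "cnr_gm": 31.6}
```

The physics-based rendering underestimates the lesion contrast (its
lesion-to-WM ratio 1.86 is the un-boosted tissue ratio); the hybrid image
recovers most of the conventional image's lesion conspicuity (3.43 vs
3.81) from only 12.5% of the conventional acquisition, and is structurally
closer to it than the physics-based image is.

The same pipeline runs from the shell:

    hybridflair run-all --seed 7 --out-dir out/
    hybridflair phantom --seed 1 --out-dir ph/
    hybridflair synth --t1 ph/t1.nii --t2 ph/t2.nii --pd ph/pd.nii --out phys.nii
    hybridflair fuse  --conv aligned.nii --phys phys.nii --mask mask.nii --accel 8 --out hybrid.nii

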