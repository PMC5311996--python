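# mjbsense

Multi-step joint-blade (MJB) SENSE reconstruction for parallel-imaging
accelerated PROPELLER MRI, with the conventional simple single-blade
(SSB) SENSE baseline, a synthetic multi-coil PROPELLER acquisition
simulator, rigid-motion estimation/correction, and a
pseudo-multiple-replica Monte-Carlo g-factor evaluation suite.

## The problem

PROPELLER acquires k-space as rotating rectangular blades (`W`
phase-encode lines x `L` readout points); the central disk shared by all
blades enables per-blade rigid-motion correction, which is why the
trajectory is popular for uncooperative patients. Parallel-imaging
acceleration (keep every `R`-th line per blade) shortens the echo train
but makes each blade's SENSE inversion ill-conditioned: with the
conventional SSB strategy each blade `i` is unaliased independently,

    P_i = C_i^+ S_i ,

where `C_i` is the `(N_c x R)` matrix of rotated coil sensitivities at
the `R` aliased positions and `S_i` the aliased coil signals, and noise
amplification grows rapidly with `R`.

MJB SENSE exploits the fact that blades share information. After the
SSB pass (Step 1), the blade-combined image — which averages many blades
per k-space sample and therefore has much higher SNR — serves as a
regularisation reference: *virtual blades* are resampled from it, and
each pixel is re-estimated by one Jacobi sweep on the SENSE normal
equations ("back-substitution"),

    rho_new = C_rho^H (S - C_others P_others^virtual) / ||C_rho||^2 ,

replacing the aliasing partners with their low-noise virtual values
(Step 2). Finally all blades are virtually widened to full width with
high-frequency data resampled from the Step-2 combined image,
co-registered, and solved jointly across all blades and coils with the
same back-substitution (Step 3). The package also implements the
ablation variants (no back-substitution in Step 3, Step 2 or Step 3
repeated) and optional Step2<->Step3 iteration.

See `docs/methods.md` for the numerical conventions, the synthetic
protocol, and known limitations.

## Worked example

```bash
mjb simulate --phantom shepp_logan --matrix 128 --coils 8 --blades 16 \
    --etl 10 --accel 5 --snr 20 --seed 0 --out data.h5
mjb recon --method ssb --in data.h5 --out ssb.nii.gz --no-motion
mjb recon --method mjb --in data.h5 --out mjb.nii.gz
```

which prints (the data set carries its ground truth, so the
reconstruction reports its error):

```
nRMS vs truth: 18.339%          # SSB
nrms_s1: 18.326%                # MJB, after Step 1 (= SSB + motion step)
nrms_s2: 10.223%                # after regularised single-blade SENSE
nrms_s3: 8.405%                 # after joint-blade SENSE (final)
nRMS vs truth: 8.405%
```

At `R = 5` and SNR 20 the joint-blade result more than halves the
reconstruction error of the per-blade baseline; Step 2 (virtual-blade
regularisation) and Step 3 (joint solve over widened blades) both
contribute. The same
pipeline is available as a library:

```python
from mjbsense import (make_phantom, make_csm, synthesize_blades,
                      undersample, add_noise, mjb_reconstruct, nrms_error)

truth = make_phantom(128)
csm = make_csm(128, 8, seed=0)
blades = undersample(synthesize_blades(truth, csm, 16, 50, 128), 5)
noisy = add_noise(blades, 20.0, truth.pixels.mean(), seed=0)
res = mjb_reconstruct(noisy, csm, truth=truth)
print(res.diagnostics["nrms_s3"])
```

The experiment runners reproduce the evaluation protocol end to end
(`mjb experiment noise`, `mjb experiment motion`, and
`mjbsense.evaluation.run_step_ablation`), reporting per-condition nRMS,
support-averaged mean g-factors from pseudo multiple replica, and
motion-recovery errors.

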