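# b1net

Complex-valued neural-network B1+ mapping and parallel-transmit (pTx)
pulse design for ultra-high-field MRI, exercised end to end on a synthetic
8-channel transceiver-coil head phantom.

## The problem

At 7T the transmit RF field (B1+) of a multi-channel head coil is complex-
valued, spatially inhomogeneous and subject-specific, so pTx pulses must
be re-calibrated from measured channel-wise B1+ maps at the start of every
session — a process that can take many minutes. `b1net` implements the
deep-learning shortcut: estimate the 8 channel-wise complex B1+ maps
directly from the CP+-mode localizer scan that is acquired anyway,

    x  in C^(128 x 96 x 9)   (8 Rx-channel complex localizer slices
                              + root-sum-of-squares magnitude)
    y  in C^(128 x 96 x 8)   (channel-wise complex B1+ maps),

with a complex-valued U-Net: four encoder/decoder stages of 3x3 complex
convolutions (features 16/32/64/128), ModReLU activations
ReLU(|z| + b) e^{i angle z}, stride-2 (up-)convolutions for resampling,
skip connections, and one 4-convolution head per transmit channel.
Training minimises a perpendicular + L2 loss on the complex maps,

    L = mean[ (Im(u* P))^2 + lambda (Re(u* P) - |T|)^2 ],   u = T/|T|,

with batch-1 Adam and an exponentially decaying learning rate. The
estimated maps feed the downstream calibration consumers: static
phase-only RF shimming (CV cost, efficiency-constrained), kt-point pulse
design (greedy k-space location selection + magnitude least squares), and
a hard-pulse Bloch simulator producing flip-angle maps.

Because acquired in-vivo libraries cannot ship with the code, the package
includes a seeded analytic phantom simulator (ellipsoidal heads inside a
jittered 8-loop transceiver array) that generates paired localizer/B1+
libraries in three slice orientations with the transceive property —
receive profiles resembling transmit profiles — that makes the estimation
problem well-posed.

## Layout

```
src/b1net/
  _autograd.py    reverse-mode autodiff over real numpy arrays
  complex_nn.py   complex conv / ModReLU / Glorot init / dropout / loss
  model.py        U-Net assembly, folds, normalisation, training, estimator
  phantom.py      transceiver-coil head phantom simulator
  metrics.py      rel. error, phase error, RMSE, SSIM, Pearson, brain mask
  ptx.py          shimming, kt-points, STA forward model, Bloch simulator
  study.py        the end-to-end desk-scale study harness
  io.py, cli.py   HDF5/NIfTI/JSON/YAML I/O and the command-line layer
docs/methods.md   model, simulator, and design-choice documentation
```
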