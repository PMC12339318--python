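"""Phasor-plot analysis and segmentation of a three-mixture image.

Transforms each pixel's decay into (G, S) coordinates at the 76 MHz laser
frequency, clusters the phasor cloud with k-means, and maps the clusters back
to the image.  Single-exponential decays fall on the universal semicircle;
mixtures fall inside it.
"""

import numpy as np

import heflim as hf
from heflim.phasor import cluster_phasor, phasor_transform, single_exp_phasor

# three vertical bands of distinct monoexponential lifetimes
shape, photons = (30, 30), 20000
acq = hf.AcquisitionConfig(image_size=shape)
taus = (400.0, 1500.0, 3500.0)
counts = np.zeros((acq.n_bins, *shape), dtype=np.int64)
for band, tau in enumerate(taus):
    cols = slice(band * 10, (band + 1) * 10)
    mean = hf.expected_decay((hf.FluorophoreComponent(tau, 1.0),), acq, photons)
    rng = np.random.default_rng(11 + band)
    counts[:, :, cols] = np.moveaxis(rng.poisson(mean, (30, 10, acq.n_bins)), 2, 0)
cube = hf.TCSPCCube(counts=counts, config=acq)

pmap = phasor_transform(cube)
assignment = cluster_phasor(pmap, k=3, seed=5)

print("cluster centers (G, S) and mean phase lifetimes, longest first:")
for (g, s), tau in zip(assignment.cluster_centers, assignment.cluster_mean_tau_m):
    print(f"  G={g:.3f} S={s:.3f}  tau={tau:7.1f} ps")
for tau in taus:
    g, s = single_exp_phasor(tau)
    print(f"theory tau={tau:6.0f} ps -> (G, S)=({g:.3f}, {s:.3f})")
# Cluster centers land near the theoretical universal-circle positions of the
# three generating lifetimes, and the segmentation recovers the bands.
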