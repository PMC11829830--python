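"""Feature-space GMM: score test structures by mixture negative log-likelihood.

A Gaussian mixture (component count chosen by BIC) is fitted to the
molecule feature vectors of one trained model; a test structure whose
features sit far from every component gets a large NLL — a rank-only
uncertainty that needs no ensemble.
"""

import numpy as np

from pesuq import SamplerConfig, ToyPES, TrainConfig, default_params, make_benchmark
from pesuq.backbone import train_model
from pesuq.gmm_uq import gmm_nll, select_gmm_bic

pes = ToyPES(default_params())
trainval, test, flags = make_benchmark(
    pes, SamplerConfig(n_samples=500, seed=8), n_test_id=200, n_test_ood=50,
)
model = train_model(
    trainval,
    TrainConfig(hidden=(48, 48), max_epochs=300, batch_size=32,
                learning_rate=3e-3),
    head="scalar",
    seed=0,
)
train_structs = [trainval[i] for i in trainval.indices("train")]
features = np.array([r.features for r in model.predict(train_structs)])
gmm = select_gmm_bic(features, range(1, 8), seed=0)
print(f"BIC selected N = {gmm.n_components} components "
      f"(BIC {gmm.bic:.0f}, {len(features)} training feature vectors)")

test_features = np.array([r.features for r in model.predict(list(test))])
nll = gmm_nll(gmm, test_features)
print(f"median NLL: held-out {np.median(nll[flags]):.1f} vs "
      f"in-distribution {np.median(nll[~flags]):.1f}")
# Larger NLL = features outside the training distribution. The NLL has no
# energy-variance scale, so it is used purely as a ranking score.
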