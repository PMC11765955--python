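"""Intra-observer variability: compare two annotation rounds and a prediction.

When the same expert annotates the same images twice, the two rounds
disagree; any prediction should be judged against that human baseline.
Here the second round and the prediction are simulated by morphologically
perturbing the truth (an annotator drawing slightly wide or narrow).
Three Dice series are reported: prediction vs round one ("old"),
prediction vs round two ("new"), and round one vs round two ("human").
"""

import numpy as np
from scipy import ndimage as ndi

from vesselseg import PhantomSpec, compare_annotation_rounds, generate_phantom

round_a, round_b, preds = {}, {}, {}
for i in range(5):
    _, truth = generate_phantom(PhantomSpec(noise_sigma=0.0, rng_seed=i))
    round_a[f"img{i}"] = truth
    # second round: systematically 1 px wider (observer drew generously)
    round_b[f"img{i}"] = ndi.binary_dilation(truth)
    # prediction: 1 px narrower than the truth
    preds[f"img{i}"] = ndi.binary_erosion(truth)

scores, summary = compare_annotation_rounds(round_a, round_b, preds)
print(summary.round(4).to_string())
# "human" Dice below 1 quantifies the annotation variability itself; a
# model whose "old"/"new" scores reach the "human" level is as consistent
# with the expert as the expert is with themselves.
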