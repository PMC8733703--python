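"""Train a small hybrid ensemble on the shake-flask design plus the
bioreactor center points and test it on the remaining bioreactor runs.

This is the scale-transfer experiment at reduced size (5 members, short
training) so it runs in well under a minute; the packaged protocol uses
10 members and longer training.
"""

from hybridoe import CvConfig, GroundTruth, TrainConfig, evaluate, fit_hybrid, make_dataset

data = make_dataset("transfer_training", GroundTruth(), seed=0)
print(f"training on {len(data['train'])} runs, testing on {len(data['test'])} bioreactor runs")

ensemble = fit_hybrid(
    data["train"],
    CvConfig(n_repeats=5, seed=1),
    TrainConfig(max_iter=60, patience=8),
    grid_step_h=1.0,
)
for split, runs in (("train", data["train"]), ("test", data["test"])):
    rep = evaluate(ensemble, runs)
    print(f"{split}: NRMSE VCC {rep['nrmse_vcc']:.1f} %, titer {rep['nrmse_titer']:.1f} %")

# Test errors a few points above the training errors indicate the model
# transfers to the 15 L scale; a large gap would mean the six inputs do
# not carry the scale-dependent kinetics.
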