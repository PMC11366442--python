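"""Train the five-class network end-to-end on synthetic beats.

Runs the full pipeline — segment, balance to a common per-class size, 80/20
stratified split, one-hot encode, train the 360-sample five-class CNN — at a
scaled-down size (500 beats, 3 epochs) so it finishes in well under a minute
on one core, and prints the per-class report.
"""

from ldcnn import (
    MITBIH5,
    PipelineConfig,
    PreprocessConfig,
    SyntheticConfig,
    TrainConfig,
    default_templates,
    generate_record,
    run_pipeline,
)

record = generate_record(
    SyntheticConfig(n_beats=500, noise_sd=0.03, seed=1), default_templates()
)
config = PipelineConfig(
    scheme=MITBIH5,
    architecture="mitbih5",
    preprocess=PreprocessConfig(),
    balance_target=100,          # Table-6-style resampling, scaled down
    test_fraction=0.2,
    seed=1,
    train=TrainConfig(epochs=3, batch_size=32, seed=1),
)
result = run_pipeline(config, record)

print("stage counts:", result.manifest["segmentation"], result.manifest["split"])
print("per-epoch test accuracy:", [round(a, 3) for a in result.history.test_accuracy])
print(result.metrics.to_markdown())
# With the synthetic morphologies the net separates all five classes almost
# perfectly within a few epochs; per-class rows mirror the published report
# layout (one-vs-rest accuracy/precision/recall/F1 in percent).
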