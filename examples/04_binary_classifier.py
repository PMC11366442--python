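"""Train the binary (Normal vs Abnormal) network on 187-sample beat rows.

Emulates the segmented beat-table distribution: each row is one beat window
of 187 samples plus a 0/1 label.  Trains the 8-conv binary CNN with its
sigmoid head and prints the threshold-0.5 confusion matrix.
"""

from ldcnn import (
    PTB2,
    SyntheticConfig,
    TrainConfig,
    binary_column,
    build_network,
    builtin_architecture,
    confusion,
    default_templates,
    generate_segment_table,
    metrics_from_confusion,
    split_train_test,
)
from ldcnn import network as net

cfg = SyntheticConfig(
    n_beats=1000,
    class_proportions={"Normal": 0.28, "Abnormal": 0.72},  # real-archive skew
    sampling_rate=125.0,
    noise_sd=0.05,
    seed=2,
)
table = generate_segment_table(cfg, default_templates(PTB2, 125.0), 187, PTB2)
split = split_train_test(table, 0.2, seed=2)

model = build_network(builtin_architecture("ptb2"), seed=2)
history = net.train(
    model,
    (split.train.windows[:, :, None], binary_column(split.train.labels)),
    (split.test.windows[:, :, None], binary_column(split.test.labels)),
    TrainConfig(epochs=5, batch_size=32, seed=2),
)
_, predicted = net.predict(model, split.test.windows[:, :, None])
cm = confusion(split.test.labels, predicted, PTB2.classes)
print("test accuracy by epoch:", [round(a, 3) for a in history.test_accuracy])
print("confusion (rows=true Normal/Abnormal):\n", cm.counts)
print(metrics_from_confusion(cm).to_markdown())
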