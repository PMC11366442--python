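"""Generate a synthetic annotated ECG record and round-trip it through WFDB.

Builds a 60-beat single-lead record at 360 Hz with the archive's heavy class
imbalance plus baseline wander, powerline interference and white noise,
writes it as WFDB files, reads it back and prints what survived the trip.
"""

import tempfile

import numpy as np

from ldcnn import (
    SyntheticConfig,
    default_templates,
    generate_record,
    read_annotations,
    read_record,
    write_record,
)

config = SyntheticConfig(n_beats=60, noise_sd=0.03, seed=42)
record = generate_record(config, default_templates())

print(f"record: {record.signal.size} samples at {record.sampling_rate:g} Hz "
      f"({record.duration_s:.1f} s), {len(record.annotations)} beats")
symbols = [a.symbol for a in record.annotations]
print("beat mix:", {s: symbols.count(s) for s in sorted(set(symbols))})

with tempfile.TemporaryDirectory() as tmp:
    hea = write_record(tmp, record)
    back = read_record(hea)
    anns = read_annotations(hea[:-3] + "atr")
    err = np.abs(back.signal - record.signal).max()
    print(f"WFDB round trip: max abs error {err:.2e} mV, "
          f"{len(anns)} annotations recovered")
# The beat mix mirrors the real archive (~75% normal); the round-trip error
# is bounded by the writer's ADC quantization step (0.5e-6 mV).
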