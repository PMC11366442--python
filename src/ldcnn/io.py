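"""Record, annotation and segment-table I/O plus class-vocabulary mapping.

Two input dialects are supported, mirroring how the benchmark databases are
distributed:

* raw mode — PhysioNet WFDB records (header + signal + annotation files),
  e.g. the MIT-BIH Arrhythmia Database: 48 two-channel 30-minute records
  sampled at 360 Hz with per-beat annotation files;
* segmented mode — headerless CSV with one beat per row: ``window_length``
  sample columns followed by one integer label column, the dialect in which
  the annotated PTB diagnostic beats circulate (187 samples per row).

Class vocabularies are fixed here:

* ``mitbih5`` — the five beat classes N, L, R, A, V (normal, left/right
  bundle branch block, atrial premature, premature ventricular contraction),
  indexed in that order; all other beat codes are excluded rather than
  pooled into a sixth class.
* ``ptb2`` — Normal (0) vs Abnormal (1); the normal beat code maps to
  Normal and every other beat code to Abnormal.
"""

from __future__ import annotations

import csv
import logging

import numpy as np
import pandas as pd

from . import wfdbio
from .containers import (
    EXCLUDE,
    BeatAnnotation,
    BeatDataset,
    ClassScheme,
    EcgRecord,
)
from .errors import IOFormatError

logger = logging.getLogger(__name__)

MITBIH5 = ClassScheme(
    name="mitbih5",
    classes=("N", "L", "R", "A", "V"),
    symbol_map={"N": "N", "L": "L", "R": "R", "A": "A", "V": "V"},
)

PTB2 = ClassScheme(
    name="ptb2",
    classes=("Normal", "Abnormal"),
    symbol_map={
        sym: ("Normal" if sym == "N" else "Abnormal")
        for sym in sorted(wfdbio.BEAT_SYMBOLS)
    },
)

SCHEMES = {s.name: s for s in (MITBIH5, PTB2)}


def map_symbol(symbol: str, scheme: ClassScheme) -> str:
    """Map a beat code to a class label of ``scheme``, or :data:`EXCLUDE`.

    Unknown or unmapped symbols are excluded (and logged), never an error:
    real annotation files contain paced beats, fusion beats and other codes
    outside the vocabulary in use.
    """
    label = scheme.symbol_map.get(symbol)
    if label is None:
        logger.debug("symbol %r not in scheme %s: excluded", symbol, scheme.name)
        return EXCLUDE
    return label


def read_record(path: str, lead: str | int = 0) -> EcgRecord:
    """Read one lead of a WFDB record in physical units (mV).

    ``lead`` selects the channel by index or by its header description
    (e.g. ``"MLII"``).  Annotations are loaded separately with
    :func:`read_annotations`.  Default lead 0 is the modified-limb lead in
    most MIT-BIH records.
    """
    header, phys = wfdbio.read_signal(path)
    if isinstance(lead, int):
        if not 0 <= lead < header.n_signals:
            raise IOFormatError(f"record {path!r} has no lead index {lead}")
        j = lead
    else:
        names = [s.description for s in header.signals]
        if lead not in names:
            raise IOFormatError(f"record {path!r} has no lead named {lead!r}; leads: {names}")
        j = names.index(lead)
    return EcgRecord(
        signal=phys[:, j],
        sampling_rate=header.sampling_rate,
        record_id=header.record_name,
    )


def write_record(directory: str, record: EcgRecord, annotation_ext: str = "atr") -> str:
    """Write a record as WFDB files (header + signal + annotations).

    Returns the header path.  The signal is stored in format 32 at a gain
    that keeps write→read round trips below 1e-6 mV.
    """
    hea = wfdbio.write_signal(
        directory, record.record_id, record.signal, record.sampling_rate
    )
    if record.annotations:
        atr = hea[: -len("hea")] + annotation_ext
        wfdbio.write_annotation_file(
            atr, [(a.sample_index, a.symbol) for a in record.annotations]
        )
    return hea


def read_annotations(path: str) -> list[BeatAnnotation]:
    """Read an annotation file, keeping beats only.

    Non-beat markers (rhythm changes '+', signal quality '~', waveform
    boundaries, comments, ...) are dropped.  Output is sorted by sample index.
    """
    pairs = wfdbio.read_annotation_file(path)
    beats = [
        BeatAnnotation(sample_index=t, symbol=sym)
        for t, sym in pairs
        if sym in wfdbio.BEAT_SYMBOLS
    ]
    beats.sort(key=lambda a: a.sample_index)
    return beats


def attach_annotations(record: EcgRecord, annotations: list[BeatAnnotation]) -> EcgRecord:
    """Return the record with annotations attached (validated against it)."""
    return EcgRecord(
        signal=record.signal,
        sampling_rate=record.sampling_rate,
        record_id=record.record_id,
        annotations=annotations,
    )


def read_segment_table(path: str, window_length: int) -> BeatDataset:
    """Read a pre-segmented beat table (CSV: samples then label, no header).

    Every row must have exactly ``window_length`` numeric sample columns plus
    one label column; ragged or non-numeric rows raise with the row number.
    Row order is preserved.  The returned scheme is ``ptb2`` when the labels
    are binary, else a generic integer vocabulary.
    """
    try:
        frame = pd.read_csv(path, header=None, dtype=np.float64)
    except OSError as exc:
        raise IOFormatError(f"cannot read segment table {path!r}: {exc}") from exc
    except ValueError as exc:
        raise IOFormatError(_locate_bad_row(path, window_length, exc)) from exc
    if frame.shape[1] != window_length + 1:
        raise IOFormatError(_locate_bad_row(path, window_length, None))
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise IOFormatError(f"{path!r}: non-numeric or missing cell in row {row}")
    windows = frame.iloc[:, :window_length].to_numpy()
    labels_f = frame.iloc[:, window_length].to_numpy()
    labels = labels_f.astype(np.int64)
    if not np.array_equal(labels_f, labels):
        raise IOFormatError(f"{path!r}: non-integer labels in last column")
    n_classes = int(labels.max()) + 1 if len(labels) else 1
    if n_classes <= 2:
        scheme = PTB2
    else:
        scheme = ClassScheme(
            name=f"int{n_classes}",
            classes=tuple(str(i) for i in range(n_classes)),
            symbol_map={},
        )
    return BeatDataset(
        windows=windows,
        labels=labels,
        scheme=scheme,
        provenance=[(path, i) for i in range(len(labels))],
    )


def _locate_bad_row(path: str, window_length: int, exc: Exception | None) -> str:
    """Re-scan a rejected CSV to name the first offending row."""
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if len(row) != window_length + 1:
                return (
                    f"{path!r}: row {i} has {len(row)} columns, "
                    f"expected {window_length} samples + 1 label"
                )
            for cell in row:
                try:
                    float(cell)
                except ValueError:
                    return f"{path!r}: non-numeric cell {cell!r} in row {i}"
    return f"{path!r}: malformed CSV ({exc})"


def write_segment_table(path: str, dataset: BeatDataset) -> None:
    """Write a BeatDataset in the segmented CSV dialect (samples, then label)."""
    table = np.column_stack([dataset.windows, dataset.labels.astype(np.float64)])
    fmt = ["%.10g"] * dataset.window_length + ["%d"]
    np.savetxt(path, table, delimiter=",", fmt=fmt)
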