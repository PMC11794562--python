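"""Database plumbing: WFDB loading, AAMI mapping, splits, experiment filters.

Beat types are grouped into the five AAMI classes — N (non-ectopic),
S (supraventricular ectopic), V (ventricular ectopic), F (fusion) and
Q (unknown/paced) — via the standard PhysioNet annotation symbols.  The
experiments keep only N/S/V: class Q is dropped, class F is dropped (it
is under 0.4% of all beats), and the MIT-BIH records containing paced
beats (102, 104, 107, 217) plus record 108 are excluded.  Record-level
train/test splits are pinned verbatim in a versioned JSON asset so no
patient straddles the two roles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from pmat import wfdb_io
from pmat.preprocessing import (AnnotatedSignal, HeartbeatRecord,
                                PipelineConfig, extract_beats,
                                remove_baseline)

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: beat symbol -> AAMI class
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

#: annotation symbols that are not beats (rhythm/quality/wave markers);
#: beat symbols outside AAMI_MAP (e.g. 'B', 'n', 'r') warn and map to Q
NON_BEAT_SYMBOLS = frozenset('~|sT*D"=p^t+u?![]@x()')

#: MIT-BIH records excluded from the experiments (paced: 102/104/107/217)
EXCLUDED_MITDB_RECORDS = frozenset({"102", "104", "107", "108", "217"})

DATABASES = ("mitdb", "incartdb", "edb")


def map_aami(beat_symbol: str) -> str | None:
    """AAMI class of a WFDB annotation symbol; None for non-beat symbols.

    Unknown beat symbols fall into class Q with a warning; the mapping is
    total and deterministic.
    """
    sym = str(beat_symbol)
    if sym in AAMI_MAP:
        return AAMI_MAP[sym]
    if sym in NON_BEAT_SYMBOLS:
        return None
    warnings.warn(f"unknown beat symbol {sym!r} mapped to Q", stacklevel=2)
    return "Q"


@dataclass
class DatasetSplit:
    """Record-level train/test split of one database (train/test disjoint)."""

    database: str
    train_records: tuple[str, ...]
    test_records: tuple[str, ...]

    def __post_init__(self):
        if set(self.train_records) & set(self.test_records):
            raise ValueError("train and test record lists overlap")


def build_split(database: str) -> DatasetSplit:
    """The pinned record lists for a database."""
    if database not in DATABASES:
        raise ValueError(f"unknown database {database!r}; one of {DATABASES}")
    text = resources.files("pmat").joinpath("data/splits.json").read_text()
    lists = json.loads(text)[database]
    return DatasetSplit(database, tuple(lists["train"]), tuple(lists["test"]))


def read_record(path: str | Path,
                lead_preference: tuple[str, ...] = ("MLII",)) -> AnnotatedSignal:
    """Load one WFDB record (header + signal + annotations) on one lead.

    ``path`` is the record prefix (no extension).  The first lead whose
    description matches ``lead_preference`` (in preference order) is used;
    a record without any preferred lead raises ``LookupError`` so callers
    can skip it with reason "lead-missing".
    """
    path = Path(path)
    header = wfdb_io.read_header(path.with_suffix(".hea"))
    leads = [s.description for s in header.signals]
    idx = None
    for wanted in lead_preference:
        if wanted in leads:
            idx = leads.index(wanted)
            break
    if idx is None:
        raise LookupError(
            f"lead-missing: record {header.record_name} has leads {leads}, "
            f"wanted one of {lead_preference}")
    signals = wfdb_io.read_signals(header, path.parent)
    annotations = wfdb_io.read_annotations(path.with_suffix(".atr"))
    samples = np.array([s for s, _ in annotations], dtype=np.int64)
    symbols = np.array([sym for _, sym in annotations])
    keep = samples < signals.shape[0]
    return AnnotatedSignal(samples=signals[:, idx],
                           sampling_rate=header.sampling_rate,
                           r_peaks=samples[keep], beat_symbols=symbols[keep])


def apply_experiment_filters(beats: list[HeartbeatRecord], database: str):
    """Retain only N/S/V beats from non-excluded records.

    Returns ``(kept, ledger)``; the ledger counts exclusions by reason and
    satisfies ``kept + sum(ledger) == len(beats)``.
    """
    kept: list[HeartbeatRecord] = []
    ledger = {"excluded-record": 0, "class-Q": 0, "class-F": 0}
    for beat in beats:
        record_id = beat.source[1]
        if database == "mitdb" and record_id in EXCLUDED_MITDB_RECORDS:
            ledger["excluded-record"] += 1
        elif beat.label == "Q":
            ledger["class-Q"] += 1
        elif beat.label == "F":
            ledger["class-F"] += 1
        else:
            kept.append(beat)
    return kept, ledger


def subsample_edb_normals(beats: list[HeartbeatRecord], per_record: int = 500,
                          seed: int = 0) -> list[HeartbeatRecord]:
    """Keep all S/V beats and at most ``per_record`` random N beats per record.

    The two-hour European ST-T records are dominated by normal beats; the
    experiments keep 500 per record, sampled uniformly and reproducibly.
    """
    rng = np.random.default_rng(seed)
    by_record: dict[str, list[int]] = {}
    for i, beat in enumerate(beats):
        if beat.label == "N":
            by_record.setdefault(beat.source[1], []).append(i)
    keep = set(range(len(beats)))
    for record_id in sorted(by_record):
        idx = by_record[record_id]
        if len(idx) > per_record:
            chosen = rng.choice(len(idx), size=per_record, replace=False)
            keep -= set(idx) - {idx[c] for c in chosen}
    return [beats[i] for i in sorted(keep)]


def prepare_database(directory: str | Path, database: str,
                     records: list[str] | None = None,
                     config: PipelineConfig | None = None,
                     seed: int = 0,
                     edb_normals_per_record: int = 500):
    """Load, filter and transform every beat of a set of WFDB records.

    Returns ``(beats, ledger)`` — the retained :class:`HeartbeatRecord`
    list after the experiment filters (and, for ``edb``, the per-record
    normal-beat subsampling) plus a per-reason exclusion ledger.
    """
    directory = Path(directory)
    if records is None:
        records = sorted(p.stem for p in directory.glob("*.hea"))
    all_beats: list[HeartbeatRecord] = []
    ledger: dict[str, int] = {}
    for record_id in records:
        prefix = directory / record_id
        if not prefix.with_suffix(".hea").exists():
            logger.warning("record %s missing; skipped", record_id)
            ledger["record-missing"] = ledger.get("record-missing", 0) + 1
            continue
        if database == "mitdb" and record_id in EXCLUDED_MITDB_RECORDS:
            ledger["excluded-record-skipped"] = \
                ledger.get("excluded-record-skipped", 0) + 1
            continue
        try:
            annotated = read_record(prefix)
        except LookupError as exc:
            logger.warning("%s", exc)
            ledger["lead-missing"] = ledger.get("lead-missing", 0) + 1
            continue
        filtered = remove_baseline(annotated)
        labels = [map_aami(sym) for sym in filtered.beat_symbols]
        beats, excl = extract_beats(filtered, labels, config,
                                    database=database, record_id=record_id)
        for k, v in excl.items():
            ledger[k] = ledger.get(k, 0) + v
        all_beats.extend(beats)
    kept, filter_ledger = apply_experiment_filters(all_beats, database)
    for k, v in filter_ledger.items():
        ledger[k] = ledger.get(k, 0) + v
    if database == "edb":
        before = len(kept)
        kept = subsample_edb_normals(kept, edb_normals_per_record, seed)
        ledger["edb-normal-subsample"] = before - len(kept)
    return kept, ledger


def beats_table(beats: list[HeartbeatRecord]) -> pd.DataFrame:
    """Feature/label table, one row per beat."""
    rows = [{
        "database": b.source[0],
        "record": b.source[1],
        "peak_sample": b.source[2],
        "pre_rr": b.features.pre_rr,
        "post_rr": b.features.post_rr,
        "local_rr": b.features.local_rr,
        "ratio_rr": b.features.ratio_rr,
        "label": b.label,
    } for b in beats]
    return pd.DataFrame(rows)


def beats_to_arrays(beats: list[HeartbeatRecord]):
    """Stack beats into (images, features, labels) arrays for the classifier."""
    images = np.stack([b.image for b in beats]).astype(np.float32)
    features = np.stack([b.features.as_array() for b in beats])
    labels = np.array([b.label for b in beats])
    return images, features, labels
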