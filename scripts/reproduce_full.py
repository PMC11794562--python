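"""Full-scale reproduction on the real PhysioNet databases (requires local data).

This script is NOT part of the automated checks: it needs the MIT-BIH
Arrhythmia (mitdb), St Petersburg INCART (incartdb) and European ST-T
(edb) records downloaded locally, and trains the CNN for many epochs.
Given the data it reproduces the filtered beat counts (93,895 for mitdb;
175,370 for incartdb) and targets the within-database and cross-database
classification experiments.

Download (no automatic fetching is performed):
    https://www.physionet.org/content/mitdb/1.0.0/
    https://physionet.org/content/incartdb/1.0.0/
    https://physionet.org/content/edb/1.0.0/

Usage:
    python scripts/reproduce_full.py --mitdb-dir DIR [--incartdb-dir DIR]
        [--edb-dir DIR] [--epochs 30] [--seed 0] --out OUTDIR
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from pmat import datasets, evaluation
from pmat.classifier import HeartbeatClassifier, ModelConfig


def prepare_split(directory, database, role, seed):
    split = datasets.build_split(database)
    records = list(split.train_records if role == "train"
                   else split.test_records)
    beats, ledger = datasets.prepare_database(directory, database,
                                              records=records, seed=seed)
    print(f"{database}/{role}: {len(beats)} beats, exclusions {ledger}")
    return beats


def run_experiment(name, train_beats, test_beats, epochs, seed, out_dir):
    images, feats, labels = datasets.beats_to_arrays(train_beats)
    model = HeartbeatClassifier(ModelConfig(epochs=epochs, seed=seed))
    model.fit(images, feats, labels, verbose=True)
    t_images, t_feats, t_labels = datasets.beats_to_arrays(test_beats)
    probs = model.predict_proba(t_images, t_feats)
    preds = np.asarray(evaluation.DEFAULT_CLASSES)[probs.argmax(axis=1)]
    results = evaluation.evaluate(t_labels, preds, probs)
    frame = evaluation.report_frame(results)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / f"{name}_report.csv", index=False)
    print(f"== {name}: accuracy {frame.attrs['accuracy_pct']:.2f}% ==")
    print(frame.to_string(index=False))
    return {"accuracy_pct": frame.attrs["accuracy_pct"],
            "n_train": len(train_beats), "n_test": len(test_beats)}


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--mitdb-dir", type=Path)
    parser.add_argument("--incartdb-dir", type=Path)
    parser.add_argument("--edb-dir", type=Path)
    parser.add_argument("--epochs", type=int, default=30)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    summary = {}
    data = {}
    for db, directory in (("mitdb", args.mitdb_dir),
                          ("incartdb", args.incartdb_dir),
                          ("edb", args.edb_dir)):
        if directory is None:
            continue
        data[db] = {}
        roles = ("test",) if db == "edb" else ("train", "test")
        for role in roles:
            data[db][role] = prepare_split(directory, db, role, args.seed)
        total = sum(len(b) for b in data[db].values())
        summary[f"{db}_beat_count"] = total
        print(f"{db}: total filtered beats {total}")

    for db in ("mitdb", "incartdb"):
        if db in data:
            summary[f"exp_{db}"] = run_experiment(
                f"within_{db}", data[db]["train"], data[db]["test"],
                args.epochs, args.seed, args.out)
    if "mitdb" in data and "incartdb" in data:
        all_mit = data["mitdb"]["train"] + data["mitdb"]["test"]
        all_inc = data["incartdb"]["train"] + data["incartdb"]["test"]
        summary["exp_mit_to_incart"] = run_experiment(
            "mit_to_incart", all_mit, all_inc, args.epochs, args.seed,
            args.out)
        summary["exp_incart_to_mit"] = run_experiment(
            "incart_to_mit", all_inc, all_mit, args.epochs, args.seed,
            args.out)
    if "mitdb" in data and "edb" in data:
        all_mit = data["mitdb"]["train"] + data["mitdb"]["test"]
        summary["exp_mit_to_edb"] = run_experiment(
            "mit_to_edb", all_mit, data["edb"]["test"], args.epochs,
            args.seed, args.out)

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
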