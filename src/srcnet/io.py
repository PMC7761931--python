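"""Plain-text persistence: cohort directories, feature tables, PANSS tables.

A cohort directory holds one sub-directory per subject containing one
tab-separated file per epoch (nodes x samples) and a ``subject.json`` sidecar
with sampling rate, node labels, group label and PANSS items.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkFeatureVector
from .panss import PanssRecord
from .preprocess import EpochSet
from .synthetic import SyntheticSubject


def write_cohort(subjects: Sequence[SyntheticSubject], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s_idx, subj in enumerate(subjects):
        sdir = out_dir / f"subject{s_idx:03d}"
        sdir.mkdir(exist_ok=True)
        for e in range(subj.epochs.n_epochs):
            np.savetxt(sdir / f"epoch{e:03d}.tsv", subj.epochs.data[e],
                       delimiter="\t", fmt="%.6f")
        sidecar = {
            "fs": subj.epochs.fs,
            "node_labels": subj.epochs.node_labels,
            "group": subj.group,
            "panss_items": subj.panss.items,
        }
        (sdir / "subject.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        paths.append(sdir)
    return paths


def read_cohort(in_dir: str | Path) -> list[SyntheticSubject]:
    in_dir = Path(in_dir)
    subjects = []
    for sdir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        sidecar = json.loads((sdir / "subject.json").read_text())
        epochs = [np.loadtxt(f, delimiter="\t", ndmin=2)
                  for f in sorted(sdir.glob("epoch*.tsv"))]
        if not epochs:
            raise FileNotFoundError(f"no epoch files in {sdir}")
        es = EpochSet(data=np.stack(epochs), fs=sidecar["fs"],
                      node_labels=list(sidecar["node_labels"]))
        subjects.append(SyntheticSubject(
            epochs=es, group=sidecar["group"],
            panss=PanssRecord(items={k: int(v) for k, v in sidecar["panss_items"].items()}),
        ))
    if not subjects:
        raise FileNotFoundError(f"no subject directories under {in_dir}")
    return subjects


def features_to_frame(
    vectors: Sequence[NetworkFeatureVector], subject_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """One row per subject, columns named ``{band}__{kind}[__{node}]``."""
    if not vectors:
        raise ValueError("no feature vectors")
    names = vectors[0].names()
    for v in vectors[1:]:
        if v.names() != names:
            raise ValueError("feature vectors have inconsistent indices")
    if subject_ids is None:
        subject_ids = [f"subject{i:03d}" for i in range(len(vectors))]
    return pd.DataFrame([v.values for v in vectors], index=list(subject_ids), columns=names)


def panss_to_frame(records: Sequence[PanssRecord],
                   subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    if subject_ids is None:
        subject_ids = [f"subject{i:03d}" for i in range(len(records))]
    return pd.DataFrame([r.items for r in records], index=list(subject_ids))
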