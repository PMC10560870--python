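"""Reading and writing the pipeline's file formats.

Count tables travel as TSV (genera as rows, samples as columns), metadata
and traits as CSV, ground-truth parameters as a JSON sidecar, posterior
draws as a compressed labelled ``.npz`` archive, and the filter log as
JSON. All readers validate what they load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gibbs import LevelDraws, PosteriorDraws

__all__ = [
    "read_count_table", "write_count_table",
    "read_samples", "write_samples",
    "read_traits", "write_traits",
    "read_blank", "write_blank",
    "write_truth", "read_truth",
    "save_draws", "load_draws",
    "write_filter_log",
]


def read_count_table(path) -> pd.DataFrame:
    """Read a genus x sample TSV count table with validation.

    The header row carries sample ids; the first column genus ids. Rejects
    empty files, duplicate ids and non-integer cells, reporting the
    offending line where possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty count table file")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        line = int(np.where(table.index == dup)[0][-1]) + 2
        raise ValueError(f"{path}: duplicate genus id '{dup}' (line {line})")
    if table.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in header")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = table.columns[[not np.issubdtype(t, np.number) for t in table.dtypes]]
        raise ValueError(f"{path}: non-numeric cells in column(s) {list(bad)}")
    if np.isnan(arr.astype(float)).any():
        row = int(np.where(np.isnan(arr.astype(float)).any(axis=1))[0][0]) + 2
        raise ValueError(f"{path}: missing cell (line {row})")
    if not np.allclose(arr, np.round(arr)):
        row = int(np.where(~np.isclose(arr, np.round(arr)).all(axis=1))[0][0]) + 2
        raise ValueError(f"{path}: non-integer count (line {row})")
    if (arr < 0).any():
        raise ValueError(f"{path}: negative counts")
    table.index.name = "genus"
    return table.astype(np.int64)


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    required = {"beekeeper", "hive", "site", "timepoint", "total_reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return frame


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path)


def read_traits(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate genus ids in trait table")
    return frame


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path)


def read_blank(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].astype(np.int64)


def write_blank(blank: pd.Series, path) -> None:
    blank.rename("blank_reads").to_csv(path, sep="\t")


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def save_draws(draws: PosteriorDraws, path) -> None:
    """Serialise posterior draws to a labelled compressed npz archive."""
    payload = {
        "beta": draws.beta, "gamma": draws.gamma, "V": draws.V,
        "chain": draws.chain,
    }
    if draws.sigma2 is not None:
        payload["sigma2"] = draws.sigma2
    for name, lev in draws.levels.items():
        payload[f"level_{name}_loadings"] = lev.loadings
        payload[f"level_{name}_eta"] = lev.eta
        payload[f"level_{name}_assignment"] = lev.sample_assignment
        payload[f"level_{name}_units"] = np.array(lev.unit_ids)
        if lev.rho is not None:
            payload[f"level_{name}_rho"] = lev.rho
    meta = {
        "kind": draws.kind,
        "predictors": draws.predictors,
        "trait_predictors": draws.trait_predictors,
        "genus_ids": draws.genus_ids,
        "sample_ids": draws.sample_ids,
        "level_names": list(draws.levels),
    }
    payload["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **payload)


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        levels = {}
        for name in meta["level_names"]:
            rho_key = f"level_{name}_rho"
            levels[name] = LevelDraws(
                name=name,
                unit_ids=list(npz[f"level_{name}_units"]),
                sample_assignment=npz[f"level_{name}_assignment"],
                loadings=npz[f"level_{name}_loadings"],
                eta=npz[f"level_{name}_eta"],
                rho=npz[rho_key] if rho_key in npz else None,
            )
        draws = PosteriorDraws(
            kind=meta["kind"], beta=npz["beta"], gamma=npz["gamma"],
            V=npz["V"], sigma2=npz["sigma2"] if "sigma2" in npz else None,
            levels=levels, chain=npz["chain"],
            predictors=meta["predictors"],
            trait_predictors=meta["trait_predictors"],
            genus_ids=meta["genus_ids"], sample_ids=meta["sample_ids"],
        )
    return draws


def write_filter_log(log, path) -> None:
    Path(path).write_text(json.dumps(log.to_dict(), indent=1))
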