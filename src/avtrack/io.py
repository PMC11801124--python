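"""Reading and writing the pipeline's on-disk formats.

Everything persists as delimited text (features, responses, coordinates,
behavior tables) plus YAML/JSON metadata, so intermediate stages stay
inspectable and reloadable.  Fitted TRF models are stored as ``.npz``
arrays with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FS, FeatureSet, NeuralResponse, SyntheticDataset, SyntheticTruth
from .trf import TRFResults

__all__ = [
    "read_wav",
    "read_lip_table",
    "write_feature_set",
    "read_feature_set",
    "write_response",
    "read_response",
    "write_dataset",
    "read_dataset",
    "write_trf",
    "read_trf",
]


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono PCM/float WAV file; returns (waveform in [-1, 1], fs)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), float(fs)


def read_lip_table(path) -> tuple[np.ndarray, str]:
    """Read a lip table: columns ``frame, axis_h, axis_v`` (axes input) or
    ``frame, x1, y1, x2, y2, ...`` (contour input).  Returns (frames
    array without the frame column, kind)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    kind = "axes" if ("axis_h" in cols or data.shape[1] == 2) else "contour"
    return data, kind


def write_feature_set(fs_obj: FeatureSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"fs": fs_obj.fs, "features": {}}
    for name, mat in fs_obj.features.items():
        fname = f"feature_{name}.tsv"
        np.savetxt(directory / fname, mat.T, delimiter="\t")
        meta["features"][name] = {"file": fname, "n_bands": int(mat.shape[0])}
    (directory / "features.yaml").write_text(yaml.safe_dump(meta))


def read_feature_set(directory) -> FeatureSet:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "features.yaml").read_text())
    feats = {}
    for name, info in meta["features"].items():
        mat = np.loadtxt(directory / info["file"], delimiter="\t", ndmin=2).T
        feats[name] = mat
    return FeatureSet(feats, fs=meta["fs"])


def write_response(resp: NeuralResponse, directory, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{stem}_data.tsv", resp.data.T, delimiter="\t")
    np.savetxt(directory / f"{stem}_coords.tsv", resp.coords, delimiter="\t")
    if resp.orientation_groups is not None:
        np.savetxt(
            directory / f"{stem}_groups.tsv", resp.orientation_groups, fmt="%d", delimiter="\t"
        )


def read_response(directory, stem: str) -> NeuralResponse:
    directory = Path(directory)
    data = np.loadtxt(directory / f"{stem}_data.tsv", delimiter="\t", ndmin=2).T
    coords = np.loadtxt(directory / f"{stem}_coords.tsv", delimiter="\t", ndmin=2)
    gfile = directory / f"{stem}_groups.tsv"
    groups = np.loadtxt(gfile, delimiter="\t", dtype=int, ndmin=2) if gfile.exists() else None
    return NeuralResponse(data, coords, orientation_groups=groups)


def write_dataset(ds: SyntheticDataset, directory) -> None:
    """Persist a synthetic dataset as delimited text plus a YAML truth
    snapshot (kernels referenced as TSV files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cond, feats in ds.features.items():
        write_feature_set(feats, directory / f"features_{cond}")
    for (subj, cond), resp in ds.responses.items():
        write_response(resp, directory / "responses", f"{subj}_{cond}")
    ds.behavior.to_csv(directory / "behavior.csv", index=False)

    t = ds.truth
    kdir = directory / "truth_kernels"
    kdir.mkdir(exist_ok=True)
    snapshot = {
        "conditions": list(ds.features),
        "condition_gains": _plain(t.condition_gains),
        "noise_sd": float(t.noise_sd),
        "noise_exponent": float(t.noise_exponent),
        "av_correlation": float(t.av_correlation),
        "behavior_effect": float(t.behavior_effect),
        "subject_intercept_sd": float(t.subject_intercept_sd),
        "behavior_noise_df": float(t.behavior_noise_df),
        "seed": int(t.seed),
        "kernels": {},
    }
    np.savetxt(kdir / "lag_ms.tsv", t.lag_ms, delimiter="\t")
    for name, kern in t.kernels.items():
        np.savetxt(kdir / f"kernel_{name}.tsv", kern, delimiter="\t")
        snapshot["kernels"][name] = f"truth_kernels/kernel_{name}.tsv"
    for name, g in t.channel_gains.items():
        np.savetxt(kdir / f"channel_gain_{name}.tsv", g, delimiter="\t")
    if t.subject_gains is not None:
        np.savetxt(kdir / "subject_gains.tsv", t.subject_gains, delimiter="\t")
    (directory / "truth.yaml").write_text(yaml.safe_dump(snapshot))


def read_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    snapshot = yaml.safe_load((directory / "truth.yaml").read_text())
    kdir = directory / "truth_kernels"
    kernels = {
        name: np.loadtxt(directory / rel, delimiter="\t", ndmin=2)
        for name, rel in snapshot["kernels"].items()
    }
    truth = SyntheticTruth(
        kernels=kernels,
        lag_ms=np.loadtxt(kdir / "lag_ms.tsv", delimiter="\t"),
        condition_gains=snapshot["condition_gains"],
        noise_sd=snapshot["noise_sd"],
        noise_exponent=snapshot["noise_exponent"],
        av_correlation=snapshot["av_correlation"],
        behavior_effect=snapshot["behavior_effect"],
        subject_intercept_sd=snapshot["subject_intercept_sd"],
        behavior_noise_df=snapshot["behavior_noise_df"],
        seed=snapshot["seed"],
    )
    gains = {}
    for name in kernels:
        f = kdir / f"channel_gain_{name}.tsv"
        if f.exists():
            gains[name] = np.loadtxt(f, delimiter="\t")
    truth.channel_gains = gains
    sg = kdir / "subject_gains.tsv"
    if sg.exists():
        truth.subject_gains = np.atleast_1d(np.loadtxt(sg, delimiter="\t"))

    conditions = snapshot.get("conditions") or sorted(
        p.name.removeprefix("features_") for p in directory.glob("features_*")
    )
    features = {c: read_feature_set(directory / f"features_{c}") for c in conditions}
    responses = {}
    for f in sorted((directory / "responses").glob("*_data.tsv")):
        stem = f.name.removesuffix("_data.tsv")
        subj, cond = stem.rsplit("_", 1)
        responses[(subj, cond)] = read_response(directory / "responses", stem)
    behavior = pd.read_csv(directory / "behavior.csv")
    return SyntheticDataset(features=features, responses=responses, behavior=behavior, truth=truth)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trf(results: TRFResults, path) -> None:
    """Save fitted TRFs as .npz arrays with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {f"kernel_{k}": v for k, v in results.kernels.items()}
    arrays.update(
        lag_ms=results.lag_ms,
        accuracies=results.accuracies,
        fold_accuracies=results.fold_accuracies,
        coefs=results.coefs,
        coords=results.coords,
    )
    if results.orientation_groups is not None:
        arrays["orientation_groups"] = results.orientation_groups
    np.savez(path, **arrays)
    meta = {
        "features": list(results.kernels),
        "basis_ms": results.basis_ms,
        "n_folds": results.n_folds,
        "step": results.step,
        "patience": results.patience,
        "meta": results.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_trf(path) -> TRFResults:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(Path(str(path) + ".json").read_text())
    kernels = {name: arrays[f"kernel_{name}"] for name in meta["features"]}
    return TRFResults(
        kernels=kernels,
        lag_ms=arrays["lag_ms"],
        basis_ms=meta["basis_ms"],
        accuracies=arrays["accuracies"],
        fold_accuracies=arrays["fold_accuracies"],
        coefs=arrays["coefs"],
        design=None,
        coords=arrays["coords"],
        orientation_groups=arrays.get("orientation_groups"),
        n_folds=meta["n_folds"],
        step=meta["step"],
        patience=meta["patience"],
        meta=meta.get("meta", {}),
    )
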