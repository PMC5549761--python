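"""Model serialization: a single HDF5 container, versioned and exact.

All arrays (d, E, R, W, A, b, class means, priors, global mean) are stored
as float64 datasets so that save -> load -> save round-trips are
byte-identical and a reloaded model produces bit-identical responses.
Timestamp tracking is disabled on every dataset for reproducible files.
The run configuration travels as a YAML string attribute and the format is
versioned; loading a file with a different major format raises with both
versions in the message.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .config import RunConfig, config_from_dict, config_to_dict
from .learning import MixtureModel, Submodel
from .preprocess import PreprocessState

import yaml

__all__ = ["FORMAT_VERSION", "save_model", "load_model"]

FORMAT_VERSION = 1

_SUB_ARRAYS = ("d", "E", "R", "W", "A", "b", "class_mean")


def save_model(model: MixtureModel, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_yaml"] = yaml.safe_dump(
            config_to_dict(model.config), sort_keys=True
        )
        f.attrs["sigma"] = float(model.sigma)
        f.attrs["lam"] = float(model.lam)
        f.attrs["seed"] = -1 if model.seed is None else int(model.seed)
        f.attrs["n_submodels"] = model.n_classes
        f.attrs["class_names"] = ",".join(model.class_names)

        def ds(name: str, arr: np.ndarray) -> None:
            f.create_dataset(name, data=np.asarray(arr, dtype=float), track_times=False)

        ds("priors", model.priors)
        ds("global_mean", model.preprocess.global_mean)
        for i, sub in enumerate(model.submodels):
            for name in _SUB_ARRAYS:
                ds(f"sub{i}_{name}", getattr(sub, name))
            f.create_dataset(
                f"sub{i}_ica_converged",
                data=bool(sub.ica_converged),
                track_times=False,
            )


def load_model(path: str | Path) -> MixtureModel:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a valid model file: {path} ({exc})") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"model format version {version} in {path} is not supported "
                f"(this build reads version {FORMAT_VERSION})"
            )
        config = config_from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        n_sub = int(f.attrs["n_submodels"])
        submodels = []
        for i in range(n_sub):
            arrays = {name: f[f"sub{i}_{name}"][()] for name in _SUB_ARRAYS}
            submodels.append(
                Submodel(**arrays, ica_converged=bool(f[f"sub{i}_ica_converged"][()]))
            )
        seed = int(f.attrs["seed"])
        model = MixtureModel(
            submodels=submodels,
            priors=f["priors"][()],
            sigma=float(f.attrs["sigma"]),
            lam=float(f.attrs["lam"]),
            preprocess=PreprocessState(
                global_mean=f["global_mean"][()], config=config.preprocess
            ),
            config=config,
            seed=None if seed == -1 else seed,
            class_names=tuple(str(f.attrs["class_names"]).split(",")),
        )
    model.validate()
    return model
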