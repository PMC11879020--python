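"""Single-file model checkpoints (config + mark set + weights).

Checkpoints are runtime artefacts for handing models between pipeline
stages; they are plain pickles of numpy arrays plus the dataclass config.
"""

from __future__ import annotations

import pickle

from epitx.models.distal import DistalModel, DistalModelConfig
from epitx.models.promoter import PromoterModel, PromoterModelConfig


def save_checkpoint(model, path) -> None:
    kind = {PromoterModel: "promoter", DistalModel: "distal"}.get(type(model))
    if kind is None:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    payload = {
        "kind": kind,
        "config": model.config,
        "mark_names": model.mark_names,
        "state": model.state_dict(),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cls = {"promoter": PromoterModel, "distal": DistalModel}[payload["kind"]]
    model = cls(payload["config"], payload["mark_names"])
    model.load_state_dict(payload["state"])
    return model
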