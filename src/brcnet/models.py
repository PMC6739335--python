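"""Loaders for case-study rule files and their documented clamp presets.

The large case-study models (CACC21, the 70-node CACC reduced to CACC49,
the 60-node T-LGL survival network reduced to T-cell54, and the 53-node
MAPK model reduced to MAPK33) are published as supplementary rule
listings that must be transcribed by hand into the rule dialect; this
package does not bundle them.  ``load_model`` accepts either a path to
such a transcription or a registered name, applies the model's
documented clamp preset, and returns both the clamped (reduced) network
and the full parse.

The bundled ``toy_synthetic`` model is a 7-node synthetic reconstruction
of the toy walkthrough network (see its .bnet header for the constraints
it reproduces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .network import BooleanNetwork, clamp_and_propagate, parse_network

__all__ = ["ModelPreset", "MODEL_PRESETS", "load_model", "LoadedModel"]


@dataclass(frozen=True)
class ModelPreset:
    name: str
    filename: str
    clamps: dict[str, int]
    bundled: bool = False
    note: str = ""


MODEL_PRESETS: dict[str, ModelPreset] = {
    "toy_synthetic": ModelPreset(
        name="toy_synthetic",
        filename="toy_synthetic.bnet",
        clamps={},
        bundled=True,
        note="7-node synthetic reconstruction of the toy walkthrough",
    ),
    "cacc21": ModelPreset(
        name="cacc21",
        filename="cacc21.bnet",
        clamps={},
        note=(
            "21-node reduced colitis-associated colon cancer network; "
            "transcribe the rules from the article's Supplementary Data 1"
        ),
    ),
    "cacc49": ModelPreset(
        name="cacc49",
        filename="cacc70.bnet",
        clamps={"DC": 1, "APC": 1},
        note=(
            "70-node colitis-associated colon cancer network with DC and "
            "APC clamped ON (premalignant epithelium in a pro-tumor "
            "microenvironment); 21 nodes fix, leaving the 49-node free "
            "subnetwork.  Transcribe the rules from the article's "
            "Supplementary Data 2"
        ),
    ),
    "tcell54": ModelPreset(
        name="tcell54",
        filename="tcell60.bnet",
        clamps={
            "Stimuli": 1,
            "IL15": 1,
            "PDGF": 1,
            "CD45": 0,
            "Stimuli2": 0,
            "TAX": 0,
        },
        note=(
            "60-node T-LGL leukemia survival-signaling network with the "
            "six input nodes clamped (Stimuli/IL15/PDGF ON; "
            "CD45/Stimuli2/TAX OFF), leaving 54 free nodes.  Transcribe "
            "the rules from the article's Supplementary Data 3"
        ),
    ),
    "mapk33": ModelPreset(
        name="mapk33",
        filename="mapk53.bnet",
        clamps={"EGFR": 1},
        note=(
            "53-node MAPK network for EGFR-overexpressing bladder cancer: "
            "EGFR clamped ON and every other input node clamped OFF "
            "(input nodes taken from the transcription's indegree-0 "
            "nodes), leaving 33 free nodes.  Transcribe the rules from "
            "the article's Supplementary Data 4"
        ),
    ),
}

# name normalization: figure labels and supplementary spellings differ in
# case (e.g. Bcatenin vs BCATENIN); lookups are case-insensitive and the
# mapping applied is recorded on the loaded model.


@dataclass
class LoadedModel:
    """A parsed model plus its clamp preset, before and after reduction."""

    name: str
    full_network: BooleanNetwork
    network: BooleanNetwork
    clamps: dict[str, int]
    fixed_assignment: dict[str, int]
    name_mapping: dict[str, str] = field(default_factory=dict)


def _resolve_clamps(
    net: BooleanNetwork, clamps: Mapping[str, int], extra_inputs_off: bool
) -> tuple[dict[str, int], dict[str, str]]:
    lower = {n.lower(): n for n in net.nodes}
    resolved: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for name, v in clamps.items():
        actual = lower.get(name.lower())
        if actual is None:
            raise KeyError(
                f"clamp preset refers to node {name!r}, absent from the "
                "transcription (check node-name spellings)"
            )
        if actual != name:
            mapping[name] = actual
        resolved[actual] = v
    if extra_inputs_off:
        # transcriptions conventionally give input nodes a self-copy rule
        for node in net.nodes:
            idx = net.index(node)
            r = net.rules[idx]
            if r.inputs == (idx,) and r.table == 0b10 and node not in resolved:
                resolved[node] = 0  # self-copying input node, default OFF
    return resolved, mapping


def load_model(name_or_path: str | Path) -> LoadedModel:
    """Load a registered model or a rule file from a path.

    Registered names apply the documented clamp preset and return the
    constant-propagated free subnetwork; unknown paths load as-is with
    no clamps.  A registered model whose transcription file is absent
    raises with the supplementary source to transcribe from.
    """
    key = str(name_or_path).lower()
    if key in MODEL_PRESETS:
        preset = MODEL_PRESETS[key]
        if preset.bundled:
            text = (
                resources.files("brcnet") / "data" / preset.filename
            ).read_text()
        else:
            path = Path(preset.filename)
            if not path.exists():
                raise FileNotFoundError(
                    f"model {preset.name!r} needs {preset.filename!r} in the "
                    f"working directory. {preset.note}."
                )
            text = path.read_text()
        full = parse_network(text)
        clamps, mapping = _resolve_clamps(
            full, preset.clamps, extra_inputs_off=(key == "mapk33")
        )
        reduced, fixed = clamp_and_propagate(full, clamps) if clamps else (
            full,
            {},
        )
        return LoadedModel(
            name=preset.name,
            full_network=full,
            network=reduced,
            clamps=clamps,
            fixed_assignment=fixed,
            name_mapping=mapping,
        )
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"no registered model and no file at {path}; registered names: "
            + ", ".join(sorted(MODEL_PRESETS))
        )
    full = parse_network(path.read_text())
    return LoadedModel(
        name=path.stem,
        full_network=full,
        network=full,
        clamps={},
        fixed_assignment={},
    )
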