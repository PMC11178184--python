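"""Load either model kind from its JSON file."""

from __future__ import annotations

import json
from pathlib import Path

from .integerized import IntegerizedModel
from .scorecard import ScorecardModel


def load_model(path: str | Path) -> IntegerizedModel | ScorecardModel:
    raw = json.loads(Path(path).read_text())
    kind = raw.get("kind")
    if kind == "integerized":
        return IntegerizedModel.from_dict(raw)
    if kind == "scorecard":
        return ScorecardModel.from_dict(raw)
    raise ValueError(f"unrecognized model kind {kind!r} in {path}")
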