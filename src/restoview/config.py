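"""Run-level configuration: one JSON-serialisable object per pipeline run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from restoview.images import ExtractionConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on besides its inputs and seed.

    Serialises losslessly to JSON; every run writes its resolved config next
    to its outputs so results can be traced back to exact settings.
    """

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    vif_threshold: float = 5.0
    protected: tuple = ("sqrt_greenery",)
    n_test: int = 10
    n_folds: int = 10
    n_lambdas: int = 100
    lambda_eps: float = 1e-4

    def to_dict(self) -> dict:
        return {
            "extraction": self.extraction.to_dict(),
            "vif_threshold": self.vif_threshold,
            "protected": list(self.protected),
            "n_test": self.n_test,
            "n_folds": self.n_folds,
            "n_lambdas": self.n_lambdas,
            "lambda_eps": self.lambda_eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            extraction=ExtractionConfig.from_dict(d.get("extraction", {})),
            vif_threshold=float(d.get("vif_threshold", 5.0)),
            protected=tuple(d.get("protected", ("sqrt_greenery",))),
            n_test=int(d.get("n_test", 10)),
            n_folds=int(d.get("n_folds", 10)),
            n_lambdas=int(d.get("n_lambdas", 100)),
            lambda_eps=float(d.get("lambda_eps", 1e-4)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
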