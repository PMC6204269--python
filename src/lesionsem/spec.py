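"""Declarative model specifications for the SEM engine.

A :class:`ModelSpec` names the latent variables and their indicators
(optionally nested: a specific factor explaining residual shared
variance of an indicator subset over and above a general factor),
residual covariances among indicators, structural paths, and covariates
entering all structural equations. Identification is per latent:
``standardize_latent`` fixes the latent (residual) variance to 1 with
all loadings free; ``fix_first_loading`` fixes the first loading to 1
with a free variance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from .errors import SpecificationError

__all__ = ["Latent", "ModelSpec"]

FREE = "free"
IDENTIFICATION_RULES = ("standardize_latent", "fix_first_loading")


@dataclass
class Latent:
    """One latent variable: name, indicators, and scaling rule.

    ``indicators`` is a list of ``(variable, loading)`` pairs where the
    loading is either the string ``"free"`` or a fixed numeric value.
    """

    name: str
    indicators: list = field(default_factory=list)
    nested_under: str | None = None
    identification: str | None = None  # None -> spec default

    def indicator_names(self) -> list[str]:
        return [v for v, _ in self.indicators]


def _norm_indicators(raw) -> list[tuple]:
    out = []
    for item in raw:
        if isinstance(item, str):
            out.append((item, FREE))
        else:
            var, loading = item
            out.append((str(var), loading if loading == FREE else float(loading)))
    return out


@dataclass
class ModelSpec:
    """Measurement blocks, structural paths, and options for one model."""

    latents: dict = field(default_factory=dict)  # name -> Latent, insertion order
    residual_covariances: list = field(default_factory=list)  # (var, var)
    paths: list = field(default_factory=list)  # (source, target)
    covariates: list = field(default_factory=list)
    identification: str = "standardize_latent"

    def __post_init__(self):
        self.validate()

    # -- construction ------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "ModelSpec":
        latents = {}
        for name, block in raw.get("latents", {}).items():
            latents[name] = Latent(
                name=name,
                indicators=_norm_indicators(block.get("indicators", [])),
                nested_under=block.get("nested_under"),
                identification=block.get("identification"),
            )
        return cls(
            latents=latents,
            residual_covariances=[tuple(p) for p in raw.get("residual_covariances", [])],
            paths=[tuple(p) for p in raw.get("paths", [])],
            covariates=list(raw.get("covariates", [])),
            identification=raw.get("identification", "standardize_latent"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_paths(self, paths: Sequence[tuple]) -> "ModelSpec":
        new = copy.deepcopy(self)
        new.paths = list(new.paths) + [tuple(p) for p in paths]
        new.validate()
        return new

    def with_covariates(self, covariates: Sequence[str]) -> "ModelSpec":
        new = copy.deepcopy(self)
        new.covariates = list(new.covariates) + list(covariates)
        new.validate()
        return new

    # -- derived sets ------------------------------------------------
    def indicator_names(self) -> list[str]:
        seen = []
        for lat in self.latents.values():
            for v in lat.indicator_names():
                if v not in seen:
                    seen.append(v)
        return seen

    def observed_names(self) -> list[str]:
        """All observed variables entering the model, indicators first."""
        obs = self.indicator_names()
        for src, tgt in self.paths:
            for v in (src, tgt):
                if v not in self.latents and v not in obs:
                    obs.append(v)
        for v in self.covariates:
            if v not in obs:
                obs.append(v)
        return obs

    def endogenous_latents(self) -> list[str]:
        targets = [t for _, t in self.paths if t in self.latents]
        if self.covariates:
            targets = targets  # covariates only ever point at existing targets
        out = []
        for name in self.latents:
            if name in targets:
                out.append(name)
        return out

    def identification_rule(self, latent: str) -> str:
        rule = self.latents[latent].identification or self.identification
        return rule

    def structural_equations(self) -> list[tuple]:
        """All (source, target) pairs including covariate paths."""
        eqs = list(self.paths)
        targets = {t for _, t in self.paths}
        for cov in self.covariates:
            for t in sorted(targets):
                eqs.append((cov, t))
        return eqs

    # -- validation --------------------------------------------------
    def validate(self):
        if not self.latents and not self.paths:
            raise SpecificationError("empty model specification")
        primary_of = {}
        nested_of = {}
        for lat in self.latents.values():
            if lat.nested_under is not None and lat.nested_under not in self.latents:
                raise SpecificationError(
                    f"latent {lat.name!r} nested under unknown latent {lat.nested_under!r}")
            if not lat.indicators and lat.name not in {t for _, t in self.paths}:
                raise SpecificationError(f"latent {lat.name!r} has no indicators")
            book = nested_of if lat.nested_under is not None else primary_of
            for v in lat.indicator_names():
                if v in book:
                    raise SpecificationError(
                        f"indicator {v!r} assigned to two "
                        f"{'nested' if book is nested_of else 'primary'} latents")
                book[v] = lat.name
        for v in nested_of:
            if v not in primary_of:
                raise SpecificationError(
                    f"indicator {v!r} loads on a nested latent but no primary latent")
        declared = set(primary_of) | set(nested_of)
        for v1, v2 in self.residual_covariances:
            if v1 not in declared or v2 not in declared:
                raise SpecificationError(
                    f"residual covariance ({v1}, {v2}) references undeclared indicators")
            if v1 == v2:
                raise SpecificationError("residual covariance must join two distinct indicators")
        for name in self.latents:
            rule = self.identification_rule(name)
            if rule not in IDENTIFICATION_RULES:
                raise SpecificationError(f"unknown identification rule {rule!r}")
        for src, tgt in self.paths:
            if tgt in self.latents:
                continue
            if tgt in declared or src in self.latents or True:
                # observed targets allowed (e.g. a mediator regressed on a
                # predictor); nothing further to check here
                continue
        if self.covariates and not self.paths:
            raise SpecificationError("covariates require at least one structural path")

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "latents": {
                name: {
                    "indicators": [[v, lo] if lo != FREE else v for v, lo in lat.indicators],
                    **({"nested_under": lat.nested_under} if lat.nested_under else {}),
                    **({"identification": lat.identification} if lat.identification else {}),
                }
                for name, lat in self.latents.items()
            },
            "residual_covariances": [list(p) for p in self.residual_covariances],
            "paths": [list(p) for p in self.paths],
            "covariates": list(self.covariates),
            "identification": self.identification,
        }

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
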