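"""Sex-specific centroid reference models.

Centroid-based diabetes subtyping assigns each individual to the nearest
cluster prototype in a standardised feature space.  The prototypes (one set
per sex) and the standardisation parameters (per-sex mean/SD in native
units, with an optional log transform per variable) together form the
*reference model*.  Centroids are configuration, not code: published
centroid coordinates are entered by the user through the YAML/JSON schema
documented here, and the package ships only a clearly labelled synthetic
demo reference for tests and documentation.

Schema (YAML or JSON)::

    variables: [age_at_diagnosis, bmi, hba1c, homa2_b, homa2_ir]
    clusters:  [SIDD, SIRD, MOD, MARD]
    transforms:            # optional, identity assumed when absent
      homa2_b: log
    sexes:
      male:
        scaling:
          age_at_diagnosis: {mean: 55.0, sd: 10.0}
          ...
        centroids:
          SIDD: [z1, z2, z3, z4, z5]
          ...
      female:
        ...
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "ReferenceModel",
    "ScaleParams",
    "StandardizedVector",
    "load_reference",
    "standardize",
    "destandardize",
]

_TRANSFORMS = ("identity", "log")


class ScaleParams(BaseModel):
    """Location/scale of one variable, in native (or log-native) units."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float

    @field_validator("sd")
    @classmethod
    def _sd_positive(cls, v: float) -> float:
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"sd must be a positive finite number, got {v}")
        return v


class SexBlock(BaseModel):
    """Scaling parameters and centroid coordinates for one sex."""

    model_config = ConfigDict(frozen=True)

    scaling: dict[str, ScaleParams]
    centroids: dict[str, tuple[float, ...]]


class ReferenceModel(BaseModel):
    """Validated centroid reference: variables, clusters, per-sex blocks.

    The order of ``variables`` fixes the coordinate order of every centroid
    vector; the order of ``clusters`` fixes the order of distance and
    probability vectors everywhere downstream (including tie-breaking).
    """

    model_config = ConfigDict(frozen=True)

    variables: tuple[str, ...]
    clusters: tuple[str, ...]
    transforms: dict[str, str] = {}
    sexes: dict[str, SexBlock]

    @field_validator("clusters")
    @classmethod
    def _clusters_ok(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2:
            raise ValueError("at least 2 clusters are required")
        if len(set(v)) != len(v):
            raise ValueError("cluster labels must be unique")
        return v

    @field_validator("variables")
    @classmethod
    def _variables_ok(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("at least one variable is required")
        if len(set(v)) != len(v):
            raise ValueError("variable names must be unique")
        return v

    @model_validator(mode="after")
    def _cross_check(self) -> "ReferenceModel":
        if not self.sexes:
            raise ValueError("at least one sex block is required")
        for var, tr in self.transforms.items():
            if var not in self.variables:
                raise ValueError(f"transform given for unknown variable {var!r}")
            if tr not in _TRANSFORMS:
                raise ValueError(
                    f"transform for {var!r} must be one of {_TRANSFORMS}, got {tr!r}"
                )
        for sex, block in self.sexes.items():
            missing = [v for v in self.variables if v not in block.scaling]
            if missing:
                raise ValueError(f"sex {sex!r}: missing scaling for {missing}")
            missing_c = [c for c in self.clusters if c not in block.centroids]
            if missing_c:
                raise ValueError(f"sex {sex!r}: missing centroids for {missing_c}")
            for cluster, coords in block.centroids.items():
                if cluster not in self.clusters:
                    raise ValueError(
                        f"sex {sex!r}: centroid for unknown cluster {cluster!r}"
                    )
                if len(coords) != len(self.variables):
                    raise ValueError(
                        f"sex {sex!r}, cluster {cluster!r}: centroid has "
                        f"{len(coords)} coordinates, expected {len(self.variables)}"
                    )
                if not all(math.isfinite(c) for c in coords):
                    raise ValueError(
                        f"sex {sex!r}, cluster {cluster!r}: non-finite centroid"
                    )
        return self

    # -- convenience accessors -------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def transform_of(self, variable: str) -> str:
        return self.transforms.get(variable, "identity")

    def centroid_matrix(self, sex: str) -> np.ndarray:
        """(K, p) array of centroids for ``sex``, rows in cluster order."""
        block = self._sex_block(sex)
        return np.array([block.centroids[c] for c in self.clusters], dtype=float)

    def scaling_arrays(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        """(locations, scales) arrays in variable order for ``sex``."""
        block = self._sex_block(sex)
        loc = np.array([block.scaling[v].mean for v in self.variables])
        scale = np.array([block.scaling[v].sd for v in self.variables])
        return loc, scale

    def _sex_block(self, sex: str) -> SexBlock:
        try:
            return self.sexes[sex]
        except KeyError:
            raise KeyError(
                f"unknown sex {sex!r}; model defines {sorted(self.sexes)}"
            ) from None


class StandardizedVector(BaseModel):
    """Feature vector on the z-scale in which centroid distances are taken."""

    model_config = ConfigDict(frozen=True)

    values: tuple[float, ...]
    sex: str

    @field_validator("values")
    @classmethod
    def _finite(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not all(math.isfinite(x) for x in v):
            raise ValueError("standardised vector has non-finite entries")
        return v

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def load_reference(source: str | Path | Mapping) -> ReferenceModel:
    """Load and validate a reference model from YAML/JSON or a mapping.

    Parameters
    ----------
    source
        Path to a ``.yaml``/``.yml``/``.json`` document, or an already
        parsed mapping following the schema in the module docstring.

    Raises
    ------
    pydantic.ValidationError or ValueError
        If any invariant fails (non-positive SD, ragged centroid, missing
        sex block, ...), naming the offending field.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a mapping at the top level")
    return ReferenceModel.model_validate(data)


def _apply_transform(x: np.ndarray, transforms: list[str]) -> np.ndarray:
    out = np.array(x, dtype=float)
    for i, tr in enumerate(transforms):
        if tr == "log":
            if out[i] <= 0:
                raise ValueError(
                    f"log transform requires a positive value, got {out[i]}"
                )
            out[i] = np.log(out[i])
    return out


def standardize(
    features: Mapping[str, float], sex: str, model: ReferenceModel
) -> StandardizedVector:
    """Standardise a raw feature mapping with the sex-specific parameters.

    ``z_i = (transform(x_i) - mean_{sex,i}) / sd_{sex,i}`` with the
    per-variable transform (identity or natural log) applied first.
    """
    missing = [v for v in model.variables if v not in features]
    if missing:
        raise ValueError(f"missing variable(s): {missing}")
    x = np.array([float(features[v]) for v in model.variables])
    if not np.all(np.isfinite(x)):
        bad = [v for v, xi in zip(model.variables, x) if not math.isfinite(xi)]
        raise ValueError(f"non-finite value(s) for: {bad}")
    loc, scale = model.scaling_arrays(sex)
    transforms = [model.transform_of(v) for v in model.variables]
    z = (_apply_transform(x, transforms) - loc) / scale
    return StandardizedVector(values=tuple(z), sex=sex)


def destandardize(z: np.ndarray, sex: str, model: ReferenceModel) -> np.ndarray:
    """Map z-scale coordinates back to native units (inverting any log)."""
    z = np.asarray(z, dtype=float)
    loc, scale = model.scaling_arrays(sex)
    x = z * scale + loc
    for i, v in enumerate(model.variables):
        if model.transform_of(v) == "log":
            x[..., i] = np.exp(x[..., i])
    return x
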