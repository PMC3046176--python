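"""Reading, writing and validation of case-control genotype datasets.

Two plain-text dialects are supported:

``gmdr_tab``
    Tab-separated with a header row: ``id``, ``pheno`` (0 = unaffected,
    1 = affected), optional covariate columns named ``cov1..covC``, then one
    column per marker holding minor-allele counts in {0, 1, 2}.

``ped_map``
    PLINK-style ``.ped``/``.map`` pair restricted to biallelic autosomal
    SNPs; the 1/2 phenotype coding is remapped to 0/1 and alleles are
    recoded as minor-allele counts.

Missing genotypes are rejected rather than imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GenotypeDataset",
    "ScenarioSpec",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "read_scenario",
    "write_scenario",
]

VALID_MODELS = ("checkerboard", "3ULM", "4ULM")


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass
class GenotypeDataset:
    """Case-control sample: phenotypes, covariates and marker genotypes.

    Genotypes are minor-allele counts (heterozygote = 1). Indices are
    0-based internally; reports use 1-based marker numbering.
    """

    subject_ids: list[str]
    phenotype: np.ndarray  # (n,) int in {0,1}; 1 = affected
    covariates: np.ndarray  # (n, c) float; c may be 0
    genotypes: np.ndarray  # (n, m) int in {0,1,2}
    marker_names: list[str]

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.subject_ids), 0))
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.subject_ids)
        if self.phenotype.shape != (n,):
            raise DataValidationError(
                f"phenotype length {self.phenotype.shape} != {n} subjects"
            )
        if self.covariates.shape[0] != n:
            raise DataValidationError(
                f"covariate rows {self.covariates.shape[0]} != {n} subjects"
            )
        if self.genotypes.shape[0] != n:
            raise DataValidationError(
                f"genotype rows {self.genotypes.shape[0]} != {n} subjects"
            )
        if self.genotypes.shape[1] != len(self.marker_names):
            raise DataValidationError("marker_names length != genotype columns")
        bad = ~np.isin(self.phenotype, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"non-binary phenotype {self.phenotype[i]} for subject "
                f"{self.subject_ids[i]} (row {i + 1})"
            )
        bad_g = ~np.isin(self.genotypes, (0, 1, 2))
        if bad_g.any():
            i, j = (int(x[0]) for x in np.nonzero(bad_g))
            raise DataValidationError(
                f"invalid genotype code {self.genotypes[i, j]} at subject "
                f"{self.subject_ids[i]} (row {i + 1}), marker "
                f"{self.marker_names[j]} (column {j + 1})"
            )
        if not np.isfinite(self.covariates).all():
            raise DataValidationError("covariates contain missing/non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.marker_names == other.marker_names
            and np.array_equal(self.phenotype, other.phenotype)
            and np.allclose(self.covariates, other.covariates)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: penetrance model plus sampling design.

    ``beta_0`` is the logistic intercept, ``beta_g`` the effect of carrying
    a high-risk multilocus genotype, ``beta_e`` the coefficient of a
    Normal(0, covariate_sd**2) covariate. The design is balanced:
    ``n_total/2`` cases and ``n_total/2`` controls.
    """

    model_name: str
    maf: float
    beta_g: float
    beta_0: float = -5.30
    beta_e: float = 1.0
    covariate_sd: float = 0.0
    n_total: int = 2000
    n_markers: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in VALID_MODELS:
            raise ValueError(f"unknown model {self.model_name!r}; expected one of {VALID_MODELS}")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.n_total < 2 or self.n_total % 2:
            raise ValueError(f"n_total must be an even integer >= 2, got {self.n_total}")
        if self.covariate_sd < 0:
            raise ValueError("covariate_sd must be nonnegative")
        k = self.n_functional
        if self.n_markers < k:
            raise ValueError(f"{self.model_name} needs at least {k} markers")

    @property
    def n_functional(self) -> int:
        return {"checkerboard": 2, "3ULM": 3, "4ULM": 4}[self.model_name]


def _parse_gmdr_tab(path: str) -> GenotypeDataset:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DataValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "id" or header[1] != "pheno":
        raise DataValidationError(
            f"{path}: gmdr_tab header must start with 'id\\tpheno', got {header[:2]}"
        )
    cov_cols = [c for c in header[2:] if c.startswith("cov")]
    n_cov = len(cov_cols)
    marker_names = header[2 + n_cov :]
    if not marker_names:
        raise DataValidationError(f"{path}: no marker columns found")
    ids, phen, covs, genos = [], [], [], []
    for r, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataValidationError(
                f"{path}: row {r} has {len(parts)} fields, expected {len(header)}"
            )
        ids.append(parts[0])
        try:
            phen.append(int(parts[1]))
        except ValueError:
            raise DataValidationError(f"{path}: row {r} phenotype {parts[1]!r} is not an integer")
        try:
            covs.append([float(v) for v in parts[2 : 2 + n_cov]])
        except ValueError:
            raise DataValidationError(f"{path}: row {r} has a non-numeric covariate")
        row_g = []
        for j, v in enumerate(parts[2 + n_cov :]):
            try:
                row_g.append(int(v))
            except ValueError:
                raise DataValidationError(
                    f"{path}: row {r} marker {marker_names[j]} value {v!r} is not an integer"
                )
        genos.append(row_g)
    return GenotypeDataset(
        subject_ids=ids,
        phenotype=np.array(phen),
        covariates=np.array(covs, dtype=float).reshape(len(ids), n_cov),
        genotypes=np.array(genos),
        marker_names=marker_names,
    )


def _parse_ped_map(path: str) -> GenotypeDataset:
    base, ext = os.path.splitext(path)
    ped_path = path if ext == ".ped" else base + ".ped"
    map_path = base + ".map"
    with open(map_path) as fh:
        marker_names = [ln.split()[1] for ln in fh if ln.strip()]
    ids, phen, allele_pairs = [], [], []
    with open(ped_path) as fh:
        for r, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(marker_names):
                raise DataValidationError(
                    f"{ped_path}: row {r} has {len(parts)} fields, expected "
                    f"{6 + 2 * len(marker_names)}"
                )
            ids.append(parts[1])
            p = parts[5]
            if p not in ("1", "2"):
                raise DataValidationError(
                    f"{ped_path}: row {r} phenotype {p!r}; expected 1 (control) or 2 (case)"
                )
            phen.append(int(p) - 1)
            allele_pairs.append(parts[6:])
    n, m = len(ids), len(marker_names)
    genos = np.zeros((n, m), dtype=np.int8)
    pairs = np.array(allele_pairs).reshape(n, m, 2)
    for j in range(m):
        col = pairs[:, j, :]
        if (col == "0").any():
            i = int(np.nonzero((col == "0").any(axis=1))[0][0])
            raise DataValidationError(
                f"{ped_path}: missing genotype for subject {ids[i]} at marker "
                f"{marker_names[j]}; missing data are rejected"
            )
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) > 2:
            raise DataValidationError(
                f"{ped_path}: marker {marker_names[j]} has {len(alleles)} alleles; "
                "only biallelic SNPs are supported"
            )
        # minor allele = lower count; tie broken alphabetically for determinism
        order = np.lexsort((alleles, counts))
        minor = alleles[order[0]] if len(alleles) == 2 else None
        if minor is not None:
            genos[:, j] = (col == minor).sum(axis=1)
    return GenotypeDataset(
        subject_ids=ids,
        phenotype=np.array(phen),
        covariates=np.empty((n, 0)),
        genotypes=genos,
        marker_names=marker_names,
    )


def read_dataset(path: str, dialect: str = "gmdr_tab") -> GenotypeDataset:
    """Read and validate a case-control dataset."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "gmdr_tab":
        return _parse_gmdr_tab(path)
    if dialect == "ped_map":
        return _parse_ped_map(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_dataset(dataset: GenotypeDataset, path: str, dialect: str = "gmdr_tab") -> None:
    """Write a dataset; the file round-trips through :func:`read_dataset`."""
    if dataset.n_subjects == 0:
        raise DataValidationError("refusing to write a dataset with no subjects")
    if dialect == "gmdr_tab":
        cov_names = [f"cov{j + 1}" for j in range(dataset.n_covariates)]
        with open(path, "w") as fh:
            fh.write("\t".join(["id", "pheno", *cov_names, *dataset.marker_names]) + "\n")
            for i in range(dataset.n_subjects):
                row = [
                    dataset.subject_ids[i],
                    str(int(dataset.phenotype[i])),
                    *(repr(float(v)) for v in dataset.covariates[i]),
                    *(str(int(g)) for g in dataset.genotypes[i]),
                ]
                fh.write("\t".join(row) + "\n")
    elif dialect == "ped_map":
        if dataset.n_covariates:
            raise DataValidationError("ped_map cannot carry covariates")
        base = os.path.splitext(path)[0]
        with open(base + ".map", "w") as fh:
            for j, name in enumerate(dataset.marker_names):
                fh.write(f"1\t{name}\t0\t{j + 1}\n")
        with open(base + ".ped", "w") as fh:
            for i in range(dataset.n_subjects):
                alleles = []
                for g in dataset.genotypes[i]:
                    # A = major, B = minor; g counts the minor allele
                    alleles += ["B"] * int(g) + ["A"] * (2 - int(g))
                fh.write(
                    "\t".join(
                        [
                            "FAM",
                            dataset.subject_ids[i],
                            "0",
                            "0",
                            "0",
                            str(int(dataset.phenotype[i]) + 1),
                            *alleles,
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_scenario(path: str) -> ScenarioSpec:
    """Read a scenario config (flat YAML mapping of ScenarioSpec fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataValidationError(f"{path}: scenario file must be a flat mapping")
    return ScenarioSpec(**raw)


def write_scenario(spec: ScenarioSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "model_name": spec.model_name,
                "maf": spec.maf,
                "beta_g": spec.beta_g,
                "beta_0": spec.beta_0,
                "beta_e": spec.beta_e,
                "covariate_sd": spec.covariate_sd,
                "n_total": spec.n_total,
                "n_markers": spec.n_markers,
                "seed": spec.seed,
            },
            fh,
            sort_keys=False,
        )
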