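"""Tabular containers and I/O for the pipeline.

Two in-memory types travel through every stage:

``IsotopeGroupTable``
    the peptide-level quantitation matrix: one row per LC-MS isotope group
    (a peptide at a given charge state and retention-time cluster) with its
    identification metadata and per-sample log2 intensities.

``CohortTable``
    per-sample genotype at one biallelic C/T SNP, sex, race and an optional
    binary treatment-response outcome (SVR / NR).

The canonical on-disk dialect is TSV with a header row; multi-valued cells
(peak centroid times, peak time scores) are comma-joined inside a single
tab-delimited field.  Lines starting with ``#`` are provenance headers and
are ignored on read.  A MATLAB v5 workspace reader/writer is provided so a
deposited ``.mat`` analysis workspace can be mapped onto the same types.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io

from .errors import DimensionError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: metadata columns of the isotope-group table, in canonical order;
#: every remaining column is a sample intensity column.
META_COLUMNS = [
    "feature_id",
    "peptide_label",
    "protein_id",
    "monoisotopic_mz",
    "charge_state",
    "peak_centroid_times",
    "peak_time_scores",
]

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}

_GENOTYPE_NORMALIZE = {"CC": "CC", "CT": "CT", "TC": "CT", "TT": "TT"}
_ALLELE_COUNT = {"CC": 2, "CT": 1, "TT": 0}
_GENOTYPE_FROM_COUNT = {2: "CC", 1: "CT", 0: "TT"}


@dataclass
class IsotopeGroupTable:
    """Peptide/isotope-group quantitation with identification metadata.

    Parameters
    ----------
    features
        DataFrame indexed by ``feature_id`` with columns ``peptide_label``
        (protein short name), ``protein_id`` (or None for unidentified
        features), ``monoisotopic_mz`` (Th), ``charge_state`` (>=1),
        ``peak_centroid_times`` and ``peak_time_scores`` (lists of floats,
        scores in [0, 1]).
    intensities
        DataFrame of log2 intensities, rows aligned to ``features`` and one
        column per sample; missing measurements are NaN.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise DimensionError("features and intensities row indices differ")
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def validate(self) -> None:
        if (self.features["charge_state"].dropna() < 1).any():
            raise ValidationError("charge_state must be >= 1")
        for scores in self.features["peak_time_scores"]:
            if any(not (0.0 <= s <= 1.0) for s in scores):
                raise ValidationError("peak_time_scores must lie in [0, 1]")

    def protein_frequency(self) -> pd.DataFrame:
        """Identified isotope groups per protein (Table-S1-style summary)."""
        identified = self.features.dropna(subset=["protein_id"])
        counts = identified.groupby("protein_id", sort=True).size()
        names = identified.groupby("protein_id", sort=True)["peptide_label"].first()
        return pd.DataFrame(
            {
                "protein_id": counts.index,
                "protein_name": names.values,
                "n_isotope_groups": counts.values,
            }
        ).reset_index(drop=True)

    def equals(self, other: "IsotopeGroupTable") -> bool:
        if self.sample_ids != other.sample_ids or self.feature_ids != other.feature_ids:
            return False
        if not np.allclose(
            self.intensities.to_numpy(),
            other.intensities.to_numpy(),
            equal_nan=True,
            rtol=0,
            atol=1e-9,
        ):
            return False
        a, b = self.features, other.features
        for col in ("peptide_label", "protein_id"):
            if not a[col].fillna("").equals(b[col].fillna("")):
                return False
        for col in ("monoisotopic_mz", "charge_state"):
            if not np.allclose(a[col].astype(float), b[col].astype(float), atol=1e-9):
                return False
        for col in ("peak_centroid_times", "peak_time_scores"):
            for u, v in zip(a[col], b[col]):
                if len(u) != len(v) or not np.allclose(u, v, atol=1e-9):
                    return False
        return True


@dataclass
class CohortTable:
    """Per-sample genotype, covariates and optional binary outcome.

    ``data`` is indexed by ``sample_id`` and carries ``genotype`` (normalized
    to CC/CT/TT; TC is the same unphased heterozygote as CT),
    ``allele_count`` (number of C alleles, 0/1/2), ``sex`` (male/female),
    ``race`` (Caucasian/African American) and ``outcome`` (SVR/NR or NaN).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def allele_counts(self) -> np.ndarray:
        """Count of C ('responder') alleles per sample."""
        return self.data["allele_count"].to_numpy(dtype=float)

    @property
    def recessive_indicator(self) -> np.ndarray:
        """1 for non-CC (TT/TC) samples: the poor-response contrast."""
        return (self.data["allele_count"].to_numpy(dtype=float) < 2).astype(float)

    @property
    def covariates(self) -> pd.DataFrame:
        """Numeric sex/race covariates: male=1, Caucasian=1."""
        return pd.DataFrame(
            {
                "sex_male": (self.data["sex"] == "male").astype(float),
                "race_caucasian": (self.data["race"] == "Caucasian").astype(float),
            },
            index=self.data.index,
        )

    @property
    def outcome01(self) -> np.ndarray:
        """SVR=1, NR=0, NaN when outcome not recorded."""
        out = self.data["outcome"]
        return out.map({"SVR": 1.0, "NR": 0.0}).to_numpy(dtype=float)

    @property
    def has_outcome(self) -> bool:
        return bool(self.data["outcome"].notna().any())

    def genotype_counts(self) -> dict[str, int]:
        vc = self.data["genotype"].value_counts()
        return {g: int(vc.get(g, 0)) for g in ("CC", "CT", "TT")}


def normalize_genotype(value: object) -> str:
    """Normalize a genotype label ('tc', 'CT', ...) to one of CC/CT/TT."""
    label = str(value).strip().upper()
    if label not in _GENOTYPE_NORMALIZE:
        raise ValidationError(f"unknown genotype string: {value!r}")
    return _GENOTYPE_NORMALIZE[label]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _sep(dialect: str) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def _parse_float(cell: str) -> float:
    if cell.strip().lower() in _MISSING_TOKENS:
        return np.nan
    return float(cell)


def _parse_float_list(cell: str) -> list[float]:
    cell = cell.strip()
    if cell.lower() in _MISSING_TOKENS:
        return []
    return [float(tok) for tok in cell.split(",")]


def provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {key}={value}" for key, value in provenance.items()]


def _read_rows(path, sep: str) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read header + data rows, skipping '#' provenance lines; keep line numbers."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=sep), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = row
            else:
                rows.append((lineno, row))
    if header is None:
        raise ParseError(f"{path}: empty file")
    return header, rows


def read_isotope_table(path, dialect: str = "tsv", log2: bool = False) -> IsotopeGroupTable:
    """Read an isotope-group quantitation table.

    Missing intensity cells (empty / NA) become NaN.  Multi-valued centroid
    time and peak-time-score cells are split on commas.  With ``log2=True``
    intensities are log2-transformed on read and non-positive values become
    missing.
    """
    sep = _sep(dialect)
    header, rows = _read_rows(path, sep)
    missing_meta = [c for c in META_COLUMNS if c not in header]
    if missing_meta:
        raise SchemaError(f"{path}: missing columns {missing_meta}")
    sample_cols = [c for c in header if c not in META_COLUMNS]
    if not sample_cols:
        raise SchemaError(f"{path}: no sample columns found")
    col_idx = {c: header.index(c) for c in header}

    meta_records, intensity_rows, index = [], [], []
    for lineno, row in rows:
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        try:
            protein_id = row[col_idx["protein_id"]].strip()
            meta_records.append(
                {
                    "peptide_label": row[col_idx["peptide_label"]].strip(),
                    "protein_id": protein_id if protein_id.lower() not in _MISSING_TOKENS else None,
                    "monoisotopic_mz": _parse_float(row[col_idx["monoisotopic_mz"]]),
                    "charge_state": int(row[col_idx["charge_state"]]),
                    "peak_centroid_times": _parse_float_list(row[col_idx["peak_centroid_times"]]),
                    "peak_time_scores": _parse_float_list(row[col_idx["peak_time_scores"]]),
                }
            )
            intensity_rows.append([_parse_float(row[col_idx[c]]) for c in sample_cols])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        index.append(row[col_idx["feature_id"]].strip())

    features = pd.DataFrame(meta_records, index=pd.Index(index, name="feature_id"))
    intensities = pd.DataFrame(
        np.asarray(intensity_rows, dtype=float),
        index=features.index,
        columns=sample_cols,
    )
    if log2:
        values = intensities.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(values > 0, np.log2(values), np.nan)
        intensities = pd.DataFrame(values, index=intensities.index, columns=sample_cols)
    return IsotopeGroupTable(features=features, intensities=intensities)


def write_isotope_table(
    table: IsotopeGroupTable, path, dialect: str = "tsv", provenance: dict | None = None
) -> None:
    sep = _sep(dialect)
    with open(path, "w", newline="") as fh:
        for line in provenance_lines(provenance):
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(META_COLUMNS + table.sample_ids)
        for fid in table.feature_ids:
            meta = table.features.loc[fid]
            row = [
                fid,
                meta["peptide_label"],
                "" if pd.isna(meta["protein_id"]) else meta["protein_id"],
                repr(float(meta["monoisotopic_mz"])),
                int(meta["charge_state"]),
                ",".join(repr(float(t)) for t in meta["peak_centroid_times"]),
                ",".join(repr(float(s)) for s in meta["peak_time_scores"]),
            ]
            for value in table.intensities.loc[fid]:
                row.append("" if pd.isna(value) else repr(float(value)))
            writer.writerow(row)


def read_cohort_table(path, dialect: str = "tsv") -> CohortTable:
    """Read per-sample genotype/sex/race/outcome; outcome column is optional."""
    sep = _sep(dialect)
    header, rows = _read_rows(path, sep)
    required = ["sample_id", "genotype", "sex", "race"]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    col_idx = {c: header.index(c) for c in header}
    has_outcome = "outcome" in header

    records, bad_rows = [], []
    for lineno, row in rows:
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        raw_geno = row[col_idx["genotype"]]
        try:
            genotype = normalize_genotype(raw_geno)
        except ValidationError:
            bad_rows.append((lineno, raw_geno))
            continue
        outcome = np.nan
        if has_outcome:
            cell = row[col_idx["outcome"]].strip()
            if cell.lower() not in _MISSING_TOKENS:
                if cell.upper() not in ("SVR", "NR"):
                    raise ValidationError(f"{path}: line {lineno}: unknown outcome {cell!r}")
                outcome = cell.upper()
        records.append(
            {
                "sample_id": row[col_idx["sample_id"]].strip(),
                "genotype": genotype,
                "allele_count": _ALLELE_COUNT[genotype],
                "sex": row[col_idx["sex"]].strip().lower(),
                "race": row[col_idx["race"]].strip(),
                "outcome": outcome,
            }
        )
    if bad_rows:
        listing = ", ".join(f"line {ln}: {g!r}" for ln, g in bad_rows)
        raise ValidationError(f"{path}: unknown genotype strings ({listing})")
    data = pd.DataFrame(records).set_index("sample_id")
    return CohortTable(data=data)


def write_cohort_table(cohort: CohortTable, path, dialect: str = "tsv", provenance: dict | None = None) -> None:
    sep = _sep(dialect)
    with open(path, "w", newline="") as fh:
        for line in provenance_lines(provenance):
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["sample_id", "genotype", "sex", "race", "outcome"])
        for sid, row in cohort.data.iterrows():
            outcome = "" if pd.isna(row["outcome"]) else row["outcome"]
            writer.writerow([sid, row["genotype"], row["sex"], row["race"], outcome])


# ---------------------------------------------------------------------------
# MAT workspace I/O
# ---------------------------------------------------------------------------


def _mat_strings(value, n: int, prefix: str) -> list[str]:
    """Coerce a loaded MAT variable (cell array / char matrix) to n strings."""
    if value is None:
        return [f"{prefix}{i:04d}" for i in range(n)]
    arr = np.atleast_1d(np.squeeze(np.asarray(value, dtype=object)))
    out = [str(np.squeeze(v)) for v in arr]
    if len(out) != n:
        raise DimensionError(f"expected {n} strings, got {len(out)}")
    return out


def read_mat_workspace(
    path, variable_map: dict[str, str]
) -> tuple[IsotopeGroupTable, CohortTable, pd.DataFrame | None]:
    """Map variables of a MATLAB v5 workspace onto the pipeline's tables.

    ``variable_map`` names which workspace variables hold which quantities.
    Required keys: ``intensities`` (features x samples matrix) and
    ``genotypes``.  Optional keys: ``feature_ids``, ``peptide_labels``,
    ``protein_ids``, ``sample_ids``, ``sex``, ``race``, ``outcome`` and
    ``scores`` (a precomputed samples x metaproteins score matrix, returned
    as the third element).  Genotypes may be strings (CC/CT/TC/TT) or C-allele
    counts 0/1/2; sex may be male/female strings or 1=male; race
    Caucasian/African American strings or 1=Caucasian; outcome SVR/NR strings
    or 1=SVR.  Workspace variables not named in the map are ignored with a
    logged warning.
    """
    try:
        workspace = scipy.io.loadmat(path, squeeze_me=False)
    except NotImplementedError as exc:  # v7.3 / HDF5 files
        raise ParseError(f"{path}: unsupported MAT version ({exc})") from exc

    def fetch(key: str, required: bool = False):
        if key not in variable_map:
            if required:
                raise SchemaError(f"variable_map is missing required key {key!r}")
            return None
        name = variable_map[key]
        if name not in workspace:
            raise SchemaError(f"mapped variable {name!r} (for {key!r}) not found in {path}")
        return workspace[name]

    unmapped = [
        name
        for name in workspace
        if not name.startswith("__") and name not in set(variable_map.values())
    ]
    if unmapped:
        logger.warning("ignoring unmapped workspace variables: %s", ", ".join(sorted(unmapped)))

    intensities = np.asarray(fetch("intensities", required=True), dtype=float)
    if intensities.ndim != 2:
        raise SchemaError("intensities variable must be a 2-D matrix")
    n_features, n_samples = intensities.shape

    feature_ids = _mat_strings(fetch("feature_ids"), n_features, "F")
    sample_ids = _mat_strings(fetch("sample_ids"), n_samples, "S")
    labels_raw = fetch("peptide_labels")
    peptide_labels = _mat_strings(labels_raw, n_features, "PEP") if labels_raw is not None else ["unknown"] * n_features
    proteins_raw = fetch("protein_ids")
    if proteins_raw is not None:
        protein_ids = [
            None if p.strip() == "" else p for p in _mat_strings(proteins_raw, n_features, "PROT")
        ]
    else:
        protein_ids = [None] * n_features

    features = pd.DataFrame(
        {
            "peptide_label": peptide_labels,
            "protein_id": protein_ids,
            "monoisotopic_mz": np.full(n_features, np.nan),
            "charge_state": np.ones(n_features, dtype=int),
            "peak_centroid_times": [[] for _ in range(n_features)],
            "peak_time_scores": [[] for _ in range(n_features)],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = IsotopeGroupTable(
        features=features,
        intensities=pd.DataFrame(intensities, index=features.index, columns=sample_ids),
    )

    genotypes_raw = np.atleast_1d(np.squeeze(fetch("genotypes", required=True)))
    if len(genotypes_raw) != n_samples:
        raise DimensionError(
            f"genotypes has {len(genotypes_raw)} entries but intensities has {n_samples} samples"
        )
    genotypes = []
    for g in genotypes_raw:
        if isinstance(g, (str, np.str_)):
            genotypes.append(normalize_genotype(g))
        else:
            count = int(np.squeeze(g))
            if count not in _GENOTYPE_FROM_COUNT:
                raise ValidationError(f"genotype allele count must be 0/1/2, got {count}")
            genotypes.append(_GENOTYPE_FROM_COUNT[count])

    def decode(key: str, one: str, zero: str, default: str) -> list:
        raw = fetch(key)
        if raw is None:
            return [default] * n_samples
        arr = np.atleast_1d(np.squeeze(raw))
        if len(arr) != n_samples:
            raise DimensionError(f"{key} has {len(arr)} entries, expected {n_samples}")
        out = []
        for v in arr:
            if isinstance(v, (str, np.str_)):
                out.append(str(v))
            else:
                out.append(one if float(np.squeeze(v)) >= 0.5 else zero)
        return out

    sex = [s.lower() for s in decode("sex", "male", "female", "female")]
    race = decode("race", "Caucasian", "African American", "Caucasian")
    outcome_raw = fetch("outcome")
    if outcome_raw is None:
        outcome = [np.nan] * n_samples
    else:
        outcome = [
            o if isinstance(o, str) else np.nan if np.isnan(float(o)) else ("SVR" if float(o) >= 0.5 else "NR")
            for o in (str(v) if isinstance(v, (str, np.str_)) else np.squeeze(v) for v in np.atleast_1d(np.squeeze(outcome_raw)))
        ]
    cohort = CohortTable(
        data=pd.DataFrame(
            {
                "genotype": genotypes,
                "allele_count": [_ALLELE_COUNT[g] for g in genotypes],
                "sex": sex,
                "race": race,
                "outcome": outcome,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    scores_raw = fetch("scores")
    scores = None
    if scores_raw is not None:
        scores_arr = np.asarray(scores_raw, dtype=float)
        if scores_arr.shape[0] != n_samples:
            raise DimensionError(
                f"scores has {scores_arr.shape[0]} rows, expected {n_samples} samples"
            )
        scores = pd.DataFrame(
            scores_arr,
            index=cohort.data.index,
            columns=[f"MP{k:03d}" for k in range(scores_arr.shape[1])],
        )
    return table, cohort, scores


def write_mat_workspace(
    table: IsotopeGroupTable,
    cohort: CohortTable,
    path,
    scores: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write a v5 MAT workspace holding the pipeline tables.

    Returns the ``variable_map`` that reads it back.  Intended for building
    synthetic stand-in workspaces in tests and demos.
    """
    payload = {
        "X": table.intensities.to_numpy(),
        "feature_ids": np.array(table.feature_ids, dtype=object),
        "peptide_labels": np.array(table.features["peptide_label"].tolist(), dtype=object),
        "protein_ids": np.array(
            ["" if pd.isna(p) else p for p in table.features["protein_id"]], dtype=object
        ),
        "sample_ids": np.array(cohort.sample_ids, dtype=object),
        "geno": cohort.allele_counts.astype(float),
        "sex": (cohort.data["sex"] == "male").to_numpy(dtype=float),
        "race": (cohort.data["race"] == "Caucasian").to_numpy(dtype=float),
    }
    variable_map = {
        "intensities": "X",
        "feature_ids": "feature_ids",
        "peptide_labels": "peptide_labels",
        "protein_ids": "protein_ids",
        "sample_ids": "sample_ids",
        "genotypes": "geno",
        "sex": "sex",
        "race": "race",
    }
    if cohort.has_outcome:
        payload["svr"] = cohort.outcome01
        variable_map["outcome"] = "svr"
    if scores is not None:
        payload["scores"] = scores.to_numpy()
        variable_map["scores"] = "scores"
    scipy.io.savemat(path, payload)
    return variable_map


def read_protein_frequency(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a protein-frequency table (protein_id, protein_name, n_isotope_groups)."""
    sep = _sep(dialect)
    header, rows = _read_rows(path, sep)
    required = ["protein_id", "protein_name", "n_isotope_groups"]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    records = []
    for lineno, row in rows:
        n_groups = int(row[idx["n_isotope_groups"]])
        if n_groups < 1:
            raise ValidationError(f"{path}: line {lineno}: n_isotope_groups must be >= 1")
        records.append(
            {
                "protein_id": row[idx["protein_id"]],
                "protein_name": row[idx["protein_name"]],
                "n_isotope_groups": n_groups,
            }
        )
    frame = pd.DataFrame(records)
    if frame["protein_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate protein_id entries")
    return frame
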