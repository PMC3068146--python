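"""Paired normal/tumour expression datasets and their synthetic generator.

The generator emulates the design of paired prostatectomy studies: every
patient contributes one morphologically normal and one tumour sample, and
carries patient-level binary endpoints (e.g. Gleason-score class, capsular
penetration).  A small set of informative genes receives an additive mean
shift between endpoint classes, optionally in only one tissue compartment —
this "tissue-specific signal" is the property the downstream specificity
swap test is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("normal", "tumour")

DEFAULT_ENDPOINTS = ("gleason", "capsular_penetration")


class InvalidConfigError(ValueError):
    """A synthetic-data configuration violates its invariants."""


class ParseError(ValueError):
    """A dataset file is malformed; the message names the offending cell."""


class PairingError(ValueError):
    """Two datasets that should be patient-paired are not."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired normal/tumour simulator.

    Parameters
    ----------
    n_patients
        Number of patients; each yields one normal and one tumour sample.
    n_genes
        Genes in the (already filtered) expression matrix.
    n_informative
        Informative genes *per endpoint*; each endpoint gets its own
        disjoint block of informative genes.
    effect_size
        Between-class mean shift of informative genes, in units of the
        per-gene noise standard deviation.
    signal_tissue
        Compartment(s) in which the class signal exists: ``"normal"``,
        ``"tumour"`` or ``"both"``.
    class_balance
        Fraction of patients in the positive class of each endpoint.
    noise_sd
        Per-gene Gaussian noise standard deviation.
    block_correlation, block_size
        Optional equicorrelated gene blocks (correlation in [0, 1)),
        letting tests probe collinearity handling.
    seed
        Seed for all randomness; identical configs give byte-identical data.
    endpoints
        Names of the binary endpoints to generate.
    """

    n_patients: int = 60
    n_genes: int = 500
    n_informative: int = 10
    effect_size: float = 1.5
    signal_tissue: str = "normal"
    class_balance: float = 0.5
    noise_sd: float = 1.0
    block_correlation: float = 0.0
    block_size: int = 10
    seed: int = 0
    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise InvalidConfigError("n_patients and n_genes must be positive")
        if self.n_informative < 0:
            raise InvalidConfigError("n_informative must be non-negative")
        if self.n_informative > self.n_genes:
            raise InvalidConfigError(
                f"n_informative={self.n_informative} exceeds n_genes={self.n_genes}"
            )
        if self.n_informative * len(self.endpoints) > self.n_genes:
            raise InvalidConfigError(
                "each endpoint needs its own disjoint informative gene block: "
                f"{self.n_informative} x {len(self.endpoints)} > {self.n_genes} genes"
            )
        if self.signal_tissue not in (*TISSUES, "both"):
            raise InvalidConfigError(f"signal_tissue {self.signal_tissue!r} not in {TISSUES + ('both',)}")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidConfigError("class_balance must be in (0, 1)")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if not 0.0 <= self.block_correlation < 1.0:
            raise InvalidConfigError("block_correlation must be in [0, 1)")
        if self.block_size < 1:
            raise InvalidConfigError("block_size must be positive")
        if self.block_size > self.n_genes:
            raise InvalidConfigError(
                f"block_size={self.block_size} exceeds n_genes={self.n_genes}"
            )
        if not self.endpoints:
            raise InvalidConfigError("at least one endpoint required")


@dataclass
class ExpressionDataset:
    """One tissue compartment's expression matrix plus sample annotation.

    ``matrix`` is samples x genes.  ``labels`` maps each endpoint name to a
    0/1 integer vector over samples.  All samples in one object share a
    single ``tissue`` tag; pairing across compartments is by ``patient_id``.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    tissue: str
    labels: dict[str, np.ndarray]
    patient_id: list[str]
    informative: dict[str, list[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x genes)")
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("matrix shape inconsistent with sample/gene ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue {self.tissue!r} not in {TISSUES}")
        if len(self.patient_id) != n:
            raise ValueError("patient_id length mismatch")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains missing values")
        for name, y in self.labels.items():
            y = np.asarray(y, dtype=int)
            if y.shape != (n,) or not np.isin(y, (0, 1)).all():
                raise ValueError(f"endpoint {name!r} is not a binary vector over samples")
            self.labels[name] = y

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def endpoint(self, name: str) -> np.ndarray:
        try:
            return self.labels[name]
        except KeyError:
            raise KeyError(
                f"endpoint {name!r} not in dataset (has {sorted(self.labels)})"
            ) from None

    def subset_samples(self, idx) -> "ExpressionDataset":
        """Dataset restricted to the given sample indices (order preserved)."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            tissue=self.tissue,
            labels={k: v[idx] for k, v in self.labels.items()},
            patient_id=[self.patient_id[i] for i in idx],
            informative=self.informative,
        )

    def gene_indices(self, gene_ids) -> np.ndarray:
        """Column indices for the given gene ids (order preserved)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.tissue == other.tissue
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.patient_id == other.patient_id
            and sorted(self.labels) == sorted(other.labels)
            and all(np.array_equal(self.labels[k], other.labels[k]) for k in self.labels)
            and np.array_equal(self.matrix, other.matrix)
        )


def check_paired(a: ExpressionDataset, b: ExpressionDataset) -> None:
    """Raise PairingError unless the two datasets share patients and labels."""
    if set(a.patient_id) != set(b.patient_id):
        raise PairingError("datasets do not share the same patient set")
    pos_a = {p: i for i, p in enumerate(a.patient_id)}
    for name in a.labels:
        if name not in b.labels:
            raise PairingError(f"endpoint {name!r} missing from second dataset")
        for j, p in enumerate(b.patient_id):
            if a.labels[name][pos_a[p]] != b.labels[name][j]:
                raise PairingError(
                    f"endpoint {name!r} disagrees across tissues for patient {p!r}"
                )


def _balanced_labels(n: int, balance: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(balance * n))
    n_pos = min(max(n_pos, 1), n - 1)  # both classes always present
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    return y


def _noise(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian baseline with optional equicorrelated blocks, sd = noise_sd."""
    eps = rng.standard_normal((n, cfg.n_genes))
    rho = cfg.block_correlation
    if rho == 0.0:
        return cfg.noise_sd * eps
    out = np.empty_like(eps)
    for start in range(0, cfg.n_genes, cfg.block_size):
        stop = min(start + cfg.block_size, cfg.n_genes)
        shared = rng.standard_normal((n, 1))
        out[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps[:, start:stop]
    return cfg.noise_sd * out


def generate_paired(cfg: SyntheticConfig) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Generate a (normal, tumour) pair of datasets from one config.

    Informative genes receive a mean shift of ``effect_size * noise_sd``
    between endpoint classes, only in the compartment(s) named by
    ``signal_tissue``; everywhere else expression is class-independent
    noise.  Labels are assigned at the patient level, so the paired
    datasets agree on every endpoint.  The planted gene ids are recorded
    in each dataset's ``informative`` attribute (in-memory ground truth;
    not part of the on-disk format).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    patients = [f"P{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    labels = {ep: _balanced_labels(n, cfg.class_balance, rng) for ep in cfg.endpoints}
    informative = {
        ep: gene_ids[j * cfg.n_informative : (j + 1) * cfg.n_informative]
        for j, ep in enumerate(cfg.endpoints)
    }

    datasets = {}
    for tissue in TISSUES:
        x = _noise(n, cfg, rng)
        if tissue == cfg.signal_tissue or cfg.signal_tissue == "both":
            shift = cfg.effect_size * cfg.noise_sd
            for j, ep in enumerate(cfg.endpoints):
                cols = slice(j * cfg.n_informative, (j + 1) * cfg.n_informative)
                x[labels[ep] == 1, cols] += shift
        datasets[tissue] = ExpressionDataset(
            matrix=x,
            gene_ids=gene_ids,
            sample_ids=[f"{p}_{tissue[0].upper()}" for p in patients],
            tissue=tissue,
            labels={ep: y.copy() for ep, y in labels.items()},
            patient_id=list(patients),
            informative=informative,
        )
    return datasets["normal"], datasets["tumour"]


# ---------------------------------------------------------------------------
# On-disk format: <prefix>.expr.tsv (genes x samples, first column gene id)
# and <prefix>.samples.tsv (sample_id, patient_id, tissue, one column per
# endpoint with values {0,1}).
# ---------------------------------------------------------------------------

def write_dataset(ds: ExpressionDataset, prefix: str) -> tuple[str, str]:
    """Write a dataset as a tab-delimited expression + annotation file pair.

    Values are written with shortest round-tripping float repr, so
    ``read_dataset(write_dataset(ds))`` is bit-identical.
    Returns (expression path, annotation path).
    """
    expr_path = f"{prefix}.expr.tsv"
    annot_path = f"{prefix}.samples.tsv"
    expr = pd.DataFrame(ds.matrix.T, index=ds.gene_ids, columns=ds.sample_ids)
    expr.index.name = "gene_id"
    expr.to_csv(expr_path, sep="\t")
    annot = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "patient_id": ds.patient_id,
            "tissue": ds.tissue,
            **{ep: ds.labels[ep] for ep in sorted(ds.labels)},
        }
    )
    annot.to_csv(annot_path, sep="\t", index=False)
    return expr_path, annot_path


def read_dataset(prefix: str) -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset`, validating as it goes."""
    expr_path = f"{prefix}.expr.tsv"
    annot_path = f"{prefix}.samples.tsv"
    expr = pd.read_csv(expr_path, sep="\t", dtype=str)
    if expr.columns[0] != "gene_id":
        raise ParseError(f"{expr_path}: first column must be 'gene_id', got {expr.columns[0]!r}")
    gene_ids = expr["gene_id"].tolist()
    dup = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()]
    if not dup.empty:
        row = int(dup.index[0]) + 2  # header is line 1
        raise ParseError(f"{expr_path}: duplicated gene id {dup.iloc[0]!r} at line {row}")
    values = expr.drop(columns="gene_id")
    # coerce pass only locates malformed cells; the payload conversion below
    # goes through numpy's correctly-rounded strtod for bit-exact round trips
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & values.notna().to_numpy())
    if values.isna().to_numpy().any() or bad.size:
        if bad.size:
            r, c = bad[0]
            raise ParseError(
                f"{expr_path}: non-numeric value {values.iat[r, c]!r} for gene "
                f"{gene_ids[r]!r} in sample column {values.columns[c]!r} (line {r + 2})"
            )
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ParseError(
            f"{expr_path}: missing value for gene {gene_ids[r]!r} in sample "
            f"column {values.columns[c]!r} (line {r + 2})"
        )

    annot = pd.read_csv(annot_path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    required = {"sample_id", "patient_id", "tissue"}
    if not required.issubset(annot.columns):
        raise ParseError(f"{annot_path}: missing columns {sorted(required - set(annot.columns))}")
    tissues = set(annot["tissue"])
    bad_tissue = tissues - set(TISSUES)
    if bad_tissue:
        row = int(annot.index[annot["tissue"].isin(bad_tissue)][0]) + 2
        raise ParseError(f"{annot_path}: invalid tissue {sorted(bad_tissue)[0]!r} at line {row}")
    if len(tissues) != 1:
        raise ParseError(f"{annot_path}: a dataset must contain a single tissue, got {sorted(tissues)}")
    sample_ids = annot["sample_id"].tolist()
    if list(values.columns) != sample_ids:
        raise ParseError(
            f"{annot_path}: sample ids do not match expression columns "
            f"({sample_ids[:3]}... vs {list(values.columns)[:3]}...)"
        )
    endpoint_cols = [c for c in annot.columns if c not in required]
    labels = {}
    for ep in endpoint_cols:
        col = pd.to_numeric(annot[ep], errors="coerce")
        if col.isna().any() or not col.isin((0, 1)).all():
            row = int(annot.index[col.isna() | ~col.isin((0, 1))][0]) + 2
            raise ParseError(f"{annot_path}: endpoint {ep!r} not binary at line {row}")
        labels[ep] = col.to_numpy(dtype=int)
    return ExpressionDataset(
        matrix=values.to_numpy().astype(np.float64).T,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        tissue=annot["tissue"].iloc[0],
        labels=labels,
        patient_id=annot["patient_id"].tolist(),
    )
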