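"""Negative-binomial count simulator with planted cell-identity structure.

Emulates the study design the pipeline validates: five myeloid cell
populations (blood monocytes, induced macrophages ``iMac``, induced
microglia-like cells ``iMG``, plus reference brain microglia and reference
monocytes from a second study), a planted microglial signature gene set
whose expression rises along the monocyte → macrophage → microglia axis,
per-gene per-study multiplicative batch effects, and heterogeneous
sequencing depths.  Counts are negative binomial with mean ``mu`` and
variance ``mu + alpha * mu**2`` (the NB2 convention shared with the
differential-expression module).

Cell types within a study differ *only* through the planted signature:
an ``effect_multipliers`` entry of ``m`` for a cell type means its
signature genes are shifted by ``m * signature_log2fc`` log2 units
relative to monocytes.  Same-identity populations from different studies
(monocyte vs ref_monocyte, iMG vs ref_microglia) are therefore
distributionally identical once the batch effect is removed — the
co-clustering the pipeline is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ConfigurationError, CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_counts",
    "generate_ct_table",
    "generate_paired_consistency_datasets",
]

KNOWN_CELL_TYPES = ("monocyte", "iMac", "iMG", "ref_microglia", "ref_monocyte")

DEFAULT_SAMPLES = {
    "monocyte": 3,
    "iMac": 3,
    "iMG": 4,
    "ref_microglia": 4,
    "ref_monocyte": 3,
}
DEFAULT_STUDIES = {
    "monocyte": "this_study",
    "iMac": "this_study",
    "iMG": "this_study",
    "ref_microglia": "reference",
    "ref_monocyte": "reference",
}
# Signature-effect dose per cell type, relative to monocytes.  iMacs sit
# halfway along the monocyte→microglia axis, mirroring their observed
# intermediate identity.
DEFAULT_EFFECT_MULTIPLIERS = {
    "monocyte": 0.0,
    "ref_monocyte": 0.0,
    "iMac": 0.5,
    "iMG": 1.0,
    "ref_microglia": 1.0,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-study experiment.

    ``dispersion`` is the NB2 ``alpha`` (variance = mu + alpha*mu^2);
    ``signature_log2fc`` is the planted log2 fold change of signature
    genes in microglia(-like) cell types versus monocytes;
    ``batch_log2shift_sd`` is the standard deviation of the per-gene,
    per-study log2-normal multiplicative batch shift; library sizes are
    drawn uniformly on ``library_size_range``.
    """

    n_genes: int = 2000
    n_signature: int = 150
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES)
    )
    studies: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STUDIES))
    effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS)
    )
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    signature_log2fc: float = 2.0
    batch_log2shift_sd: float = 0.25
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.samples_per_group)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        if not (1 <= self.n_signature <= self.n_genes):
            raise ConfigurationError("n_signature must satisfy 1 <= n_signature <= n_genes")
        if not self.samples_per_group:
            raise ConfigurationError("samples_per_group must name at least one cell type")
        for ct, n in self.samples_per_group.items():
            if ct not in KNOWN_CELL_TYPES:
                raise ConfigurationError(
                    f"samples_per_group: unknown cell type {ct!r}; "
                    f"expected one of {KNOWN_CELL_TYPES}"
                )
            if n < 1:
                raise ConfigurationError(f"samples_per_group[{ct!r}] must be >= 1")
            if ct not in self.studies:
                raise ConfigurationError(f"studies: no study label for cell type {ct!r}")
            if ct not in self.effect_multipliers:
                raise ConfigurationError(
                    f"effect_multipliers: no entry for cell type {ct!r}"
                )
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.batch_log2shift_sd < 0:
            raise ConfigurationError("batch_log2shift_sd must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                "library_size_range must be positive with range[0] <= range[1]"
            )


@dataclass
class SyntheticStudy:
    """Generated counts plus the planted ground truth."""

    counts: CountMatrix
    truth_signature: frozenset[str]
    truth_log2fc: pd.Series
    truth_batch: pd.Series

    @property
    def signature_gene_ids(self) -> list[str]:
        return sorted(self.truth_signature)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 sampling via the gamma–Poisson mixture."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def generate_counts(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic two-study count matrix with known truth.

    The per-gene baseline mean is log-normal around ``baseline_mean``;
    signature genes get ``effect_multipliers[cell_type] *
    signature_log2fc`` added on the log2 scale; each (gene, study) pair
    gets an independent ``N(0, batch_log2shift_sd)`` log2 shift; each
    sample's expected column sum is scaled to its drawn library size.
    All randomness flows from one generator seeded with ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    sig_idx = rng.choice(config.n_genes, size=config.n_signature, replace=False)
    sig_mask = np.zeros(config.n_genes, dtype=bool)
    sig_mask[sig_idx] = True

    # heterogeneous baselines: log-normal, rescaled to mean baseline_mean
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base *= config.baseline_mean / base.mean()

    study_labels = sorted(set(config.studies[ct] for ct in config.samples_per_group))
    batch_shift = {
        st: rng.normal(0.0, config.batch_log2shift_sd, size=config.n_genes)
        for st in study_labels
    }

    sample_ids: list[str] = []
    cell_types: list[str] = []
    studies: list[str] = []
    columns: list[np.ndarray] = []
    for ct in config.samples_per_group:
        n = config.samples_per_group[ct]
        study = config.studies[ct]
        mult = config.effect_multipliers[ct]
        log2_mu = np.log2(base) + batch_shift[study]
        log2_mu = log2_mu + np.where(sig_mask, mult * config.signature_log2fc, 0.0)
        mu_profile = np.power(2.0, log2_mu)
        for rep in range(1, n + 1):
            lib = rng.uniform(*config.library_size_range)
            mu = mu_profile * (lib / mu_profile.sum())
            columns.append(_nb_draw(rng, mu, config.dispersion))
            sample_ids.append(f"{ct}_{rep}")
            cell_types.append(ct)
            studies.append(study)

    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(
        {"cell_type": cell_types, "study": studies}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth_log2fc = pd.Series(
        np.where(sig_mask, config.signature_log2fc, 0.0), index=genes, name="log2fc"
    )
    return SyntheticStudy(
        counts=CountMatrix(counts, meta),
        truth_signature=frozenset(genes[sig_mask]),
        truth_log2fc=truth_log2fc,
        truth_batch=meta["study"].rename("batch"),
    )


def generate_paired_consistency_datasets(
    n_genes: int = 2000,
    n_concordant: int = 80,
    n_discordant: int = 40,
    n_signature: int = 200,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    samples_per_group: int = 20,
    baseline_mean: float = 50.0,
    seed: int = 0,
):
    """Two studies with planted concordant and discordant signature genes.

    Builds a test dataset (monocytes vs iMG) and a reference dataset
    (monocytes vs brain microglia) sharing one gene universe.  Within a
    signature of ``n_signature`` genes, ``n_concordant`` genes move by
    ``effect_log2fc`` log2 units in the *same* direction in both
    studies, ``n_discordant`` move by the same magnitude in *opposite*
    directions, and the rest are unchanged — ground truth for
    consistency-score recovery.

    Returns ``(test, ref, signature, concordant, discordant)`` where the
    matrices are :class:`~imglia.containers.CountMatrix`, ``signature``
    a :class:`~imglia.containers.GeneList` and the last two are frozen
    gene-id sets.
    """
    from .containers import GeneList

    if n_concordant + n_discordant > n_signature or n_signature > n_genes:
        raise ConfigurationError(
            "need n_concordant + n_discordant <= n_signature <= n_genes"
        )
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= baseline_mean / base.mean()

    sig_idx = rng.choice(n_genes, size=n_signature, replace=False)
    conc_idx = sig_idx[:n_concordant]
    disc_idx = sig_idx[n_concordant : n_concordant + n_discordant]
    eff_test = np.zeros(n_genes)
    eff_ref = np.zeros(n_genes)
    eff_test[conc_idx] = effect_log2fc
    eff_ref[conc_idx] = effect_log2fc
    eff_test[disc_idx] = effect_log2fc
    eff_ref[disc_idx] = -effect_log2fc

    def _dataset(
        prefix: str, monocyte_label: str, microglia_label: str, effects: np.ndarray
    ) -> CountMatrix:
        cols, meta_ct = {}, {}
        for ct, eff_on in ((monocyte_label, False), (microglia_label, True)):
            mu_profile = base * np.power(2.0, effects if eff_on else 0.0)
            for rep in range(1, samples_per_group + 1):
                sid = f"{prefix}_{ct}_{rep}"
                cols[sid] = _nb_draw(rng, mu_profile, dispersion)
                meta_ct[sid] = ct
        counts = pd.DataFrame(cols, index=genes)
        meta = pd.DataFrame(
            {"cell_type": pd.Series(meta_ct), "study": prefix},
        )
        meta.index.name = "sample_id"
        return CountMatrix(counts, meta)

    test = _dataset("test", "monocyte", "iMG", eff_test)
    ref = _dataset("ref", "ref_monocyte", "ref_microglia", eff_ref)
    signature = GeneList.from_symbols("planted_signature", genes[sig_idx])
    return test, ref, signature, frozenset(genes[conc_idx]), frozenset(genes[disc_idx])


def generate_ct_table(
    n_replicates: int,
    target_delta_ct: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    housekeeping_ct: float = 15.0,
) -> pd.DataFrame:
    """Simulate a qPCR CT table for the 2^-ddCT readout.

    ``target_delta_ct`` maps condition → true ΔCT (target CT minus
    housekeeping CT).  Gaussian cycle noise of ``noise_sd`` is added to
    every measured CT independently.  Returns the long-format table the
    qpcr module reads: columns (condition, replicate, gene, ct).
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if not target_delta_ct:
        raise ConfigurationError("target_delta_ct must name at least one condition")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, dct in target_delta_ct.items():
        for rep in range(1, n_replicates + 1):
            hk = housekeeping_ct + rng.normal(0.0, noise_sd)
            tg = housekeeping_ct + dct + rng.normal(0.0, noise_sd)
            rows.append((condition, rep, "housekeeping", hk))
            rows.append((condition, rep, "target", tg))
    return pd.DataFrame(rows, columns=["condition", "replicate", "gene", "ct"])
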