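"""In-memory genotype container used by every stage.

Calls are stored as an ``int8`` matrix of alternate-allele dosages
(individuals x variants) with ``-1`` for missing; per-variant metadata
(chromosome, 1-based position, alleles, optional imputation r2 and allele
frequency) lives in a parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

REQUIRED_VARIANT_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


class GenotypeMatrix:
    def __init__(
        self,
        samples: Sequence[str],
        variants: pd.DataFrame,
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, "
                f"n_variants={len(variants)})"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2} or -1 (missing)")
        for col in REQUIRED_VARIANT_COLS:
            if col not in variants.columns:
                raise ValueError(f"variant table lacks required column {col!r}")
        if variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        self.samples: List[str] = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.variants = variants.reset_index(drop=True)
        self.calls = calls

    # -- basic views -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), self.variants.copy(), self.calls.copy()
        )

    def subset(
        self,
        samples: Optional[Sequence[str]] = None,
        variant_mask: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        calls = self.calls
        sample_list = self.samples
        if samples is not None:
            idx = self.sample_index(samples)
            calls = calls[idx, :]
            sample_list = list(samples)
        variants = self.variants
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            calls = calls[:, variant_mask]
            variants = variants.loc[variant_mask].reset_index(drop=True)
        return GenotypeMatrix(sample_list, variants.copy(), calls.copy())

    # -- summaries -------------------------------------------------------

    def sample_call_rate(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return (self.calls != MISSING).mean(axis=0)

    def alt_freq(self, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        calls = self.calls
        if sample_ids is not None:
            calls = calls[self.sample_index(sample_ids), :]
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return freq

    def maf(self, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        p = self.alt_freq(sample_ids)
        return np.minimum(p, 1.0 - p)

    def dosage_frame(self) -> pd.DataFrame:
        """Float dosage frame (samples x variant_id) with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return pd.DataFrame(d, index=self.samples, columns=self.variants["variant_id"])
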