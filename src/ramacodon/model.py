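"""Model/Results surface over the synonymous-codon comparison pipeline.

``SynonymousCodonTest`` is built from per-(codon, secondary structure)
dihedral samples (directly, or from aggregated protein records); ``fit``
runs every synonymous-pair and self-pair bootstrap permutation test with
per-structure Benjamini-Hochberg correction and returns a
``CodonTestResults`` carrying the per-pair distances, p-values, FDR
decisions and a ``summary()`` table.  Plotting of distance matrices and
uncertainty-MDS layouts hangs off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .genetics import GeneticCode
from .inference import normalize_distance_matrix, run_all_pairwise_tests

__all__ = ["SynonymousCodonTest", "CodonTestResults"]


class SynonymousCodonTest:
    """Pairwise comparison of synonymous codon dihedral distributions.

    Parameters
    ----------
    samples : iterable of CodonSample
        Pooled (phi, psi) observations per codon and secondary structure.
    config : RunConfig, optional
        Statistical parameters; defaults are the standard analysis values.
    genetic_code : GeneticCode, optional
    """

    def __init__(self, samples, config: RunConfig | None = None,
                 genetic_code: GeneticCode | None = None):
        self.samples = list(samples)
        self.config = config or RunConfig()
        self.genetic_code = genetic_code or GeneticCode()

    @classmethod
    def from_records(cls, records, config: RunConfig | None = None,
                     ss_classes=("E", "H")):
        """Build the model from aggregated protein records."""
        from .dataset import extract_codon_samples

        pools = extract_codon_samples(records, ss_classes)
        return cls(pools.values(), config)

    def fit(self, seed: int | None = None) -> "CodonTestResults":
        """Run all pairwise tests; ``seed`` overrides the config seed."""
        config = self.config if seed is None else self.config.replace(seed=seed)
        table, decisions = run_all_pairwise_tests(
            self.samples, config, self.genetic_code)
        return CodonTestResults(self, config, table, decisions)


class CodonTestResults:
    """Fitted results: per-pair distances, p-values and FDR decisions."""

    def __init__(self, model, config, table: pd.DataFrame, decisions: dict):
        self.model = model
        self.config = config
        self.table = table
        self.decisions = decisions

    def distance_matrix(self, amino_acid: str, secondary_structure: str):
        """(codons, raw, normalized) mean-distance matrices for one group."""
        sub = self.table[
            (self.table.amino_acid == amino_acid)
            & (self.table.secondary_structure == secondary_structure)
        ]
        if sub.empty:
            raise KeyError(f"no tests for {amino_acid}/{secondary_structure}")
        codons = sorted(set(sub.codon_a) | set(sub.codon_b))
        n = len(codons)
        raw = np.zeros((n, n))
        for row in sub.itertuples():
            i, j = codons.index(row.codon_a), codons.index(row.codon_b)
            raw[i, j] = raw[j, i] = row.mean_distance
        return codons, raw, normalize_distance_matrix(raw)

    def mds_layout(self, amino_acid: str, secondary_structure: str):
        from .embedding_viz import uncertainty_mds

        codons, raw, _ = self.distance_matrix(amino_acid, secondary_structure)
        return codons, uncertainty_mds(raw)

    def plot_pvalues(self, secondary_structure: str, output_path):
        from .embedding_viz import plot_pvalue_bh_curve

        sub = self.table[self.table.secondary_structure == secondary_structure]
        pvals = [((r.codon_a, r.codon_b), r.p_value) for r in sub.itertuples()]
        plot_pvalue_bh_curve(pvals, self.config.q, output_path,
                             self.decisions.get(secondary_structure))

    def plot_mds(self, amino_acid: str, secondary_structure: str, output_path):
        from .embedding_viz import plot_mds

        codons, layout = self.mds_layout(amino_acid, secondary_structure)
        plot_mds(layout, codons, output_path)

    def save_table(self, path):
        """Tab-delimited results with the config echoed into the header."""
        with open(path, "w") as fh:
            for line in self.config.header_lines():
                fh.write(line + "\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def summary(self) -> str:
        lines = ["Synonymous codon dihedral-distribution comparison", ""]
        lines += [ln.lstrip("# ") for ln in self.config.header_lines()]
        lines.append("")
        for ss, dec in sorted(self.decisions.items()):
            sub = self.table[self.table.secondary_structure == ss]
            n_self = int((sub.codon_a == sub.codon_b).sum())
            n_pair = len(sub) - n_self
            rej_pairs = sub[(sub.codon_a != sub.codon_b) & sub.rejected]
            rej_self = sub[(sub.codon_a == sub.codon_b) & sub.rejected]
            thr = "none" if dec.alpha_M is None else f"{dec.alpha_M:.4g}"
            lines.append(
                f"structure {ss}: {len(sub)} tests "
                f"({n_self} self-controls, {n_pair} synonymous pairs); "
                f"BH threshold {thr}; "
                f"rejected {len(rej_pairs)}/{n_pair} pairs, "
                f"{len(rej_self)}/{n_self} controls"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (f"<CodonTestResults: {len(self.table)} tests, "
                f"{sum(len(d.rejected) for d in self.decisions.values())} "
                f"rejections>")
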