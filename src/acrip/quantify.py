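"""Per-mRNA FE/FC statistics and TPM/FOT normalizations.

The mRNA-level fold enrichment is the sum of the FE values of that mRNA's
peaks; the mRNA fold change is pseudocounted, FC = (FE_b + 1)/(FE_a + 1),
so that mRNAs absent from one group (FE = 0 there) still get a finite,
meaningful fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .filters import ConsensusPeak
from .genome import TranscriptAnnotation
from .matrix import OmicsMatrix
from .peaks import SamplePeak


# ---------------------------------------------------------------------------
# mRNA-level FE and FC
# ---------------------------------------------------------------------------

def gene_fe(cons_peaks: list[ConsensusPeak]) -> dict[str, float]:
    """Sum of consensus-peak FEs per host gene (genes without peaks absent)."""
    out: dict[str, float] = {}
    for pk in cons_peaks:
        if pk.host_gene is None:
            continue
        out[pk.host_gene] = out.get(pk.host_gene, 0.0) + pk.fe
    return out


def gene_fc(fe_b: float, fe_a: float) -> float:
    """Pseudocounted mRNA fold change (FE_b + 1) / (FE_a + 1).

    Undetected mRNAs contribute FE = 0, so group-exclusive mRNAs still get
    a finite fold change (this is exactly the zero-denominator case the
    pseudocount exists for).
    """
    return (fe_b + 1.0) / (fe_a + 1.0)


def gene_fe_fc_table(
    cons_a: list[ConsensusPeak],
    cons_b: list[ConsensusPeak],
    groups: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene FE of each group, detection flags, FC and Venn class."""
    fe_a, fe_b = gene_fe(cons_a), gene_fe(cons_b)
    genes = sorted(set(fe_a) | set(fe_b))
    rows = []
    for g in genes:
        a, b = fe_a.get(g, 0.0), fe_b.get(g, 0.0)
        det_a, det_b = g in fe_a, g in fe_b
        if det_a and det_b:
            klass = "Overlay"
        elif det_a:
            klass = f"{groups[1]} absent"
        else:
            klass = f"{groups[1]} unique"
        rows.append((g, a, b, det_a, det_b, gene_fc(b, a), klass))
    return pd.DataFrame(
        rows,
        columns=["gene", f"fe_{groups[0]}", f"fe_{groups[1]}",
                 f"detected_{groups[0]}", f"detected_{groups[1]}", "fc", "venn_class"],
    ).set_index("gene")


def replicate_gene_fe(
    sample_peaks: list[SamplePeak], samples: list[str]
) -> pd.DataFrame:
    """Per-replicate mRNA FE: sum of that replicate's calibrated peak FEs.

    Genes x samples table over all listed samples; a gene with no peak in a
    replicate gets 0 there.  Feeds the overlay moderated test on the
    log2(FE + 1) scale.
    """
    genes = sorted({p.host_gene for p in sample_peaks if p.host_gene})
    df = pd.DataFrame(0.0, index=genes, columns=samples)
    for pk in sample_peaks:
        if pk.host_gene is None or pk.sample not in df.columns:
            continue
        df.loc[pk.host_gene, pk.sample] += pk.fe
    return df


# ---------------------------------------------------------------------------
# Expression normalizations
# ---------------------------------------------------------------------------

def tpm(counts: OmicsMatrix, ann: TranscriptAnnotation) -> OmicsMatrix:
    """Transcripts per million: 1e6 * (c_g / L_g) / sum_j (c_j / L_j).

    Gene length L_g is the union exon length of the gene's longest
    transcript.  A sample whose length-normalized total is zero is an
    error (TPM undefined).
    """
    lengths = pd.Series({g: ann.gene_length(g) for g in counts.features}, dtype=float)
    rate = counts.values.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ConfigError(f"sample {bad!r}: all-zero counts, TPM undefined")
    return OmicsMatrix(rate.div(totals, axis=1) * 1e6, kind="tpm")


def fot(intensities: OmicsMatrix) -> OmicsMatrix:
    """Fraction-of-total normalization, scaled by 1e6; missing stays missing."""
    totals = intensities.values.sum(axis=0, skipna=True)
    n_obs = intensities.values.notna().sum(axis=0)
    if (n_obs == 0).any():
        bad = n_obs.index[n_obs == 0][0]
        raise ConfigError(f"sample {bad!r}: all values missing, FOT undefined")
    return OmicsMatrix(intensities.values.div(totals, axis=1) * 1e6, kind="fot")


# ---------------------------------------------------------------------------
# Detection rules
# ---------------------------------------------------------------------------

def rna_detected_genes(
    counts: OmicsMatrix, group: str, *, min_count: int = 1, min_replicates: int = 2
) -> set[str]:
    """Genes with raw count > min_count in at least min_replicates replicates."""
    cols = counts.samples_of_group(group)
    ok = (counts.values[cols] > min_count).sum(axis=1) >= min_replicates
    return set(counts.values.index[ok])


def protein_detected(
    intensities: OmicsMatrix, group: str, *, min_replicates: int = 1
) -> set[str]:
    """Proteins with a non-missing value in >= min_replicates of the group."""
    cols = intensities.samples_of_group(group)
    ok = intensities.values[cols].notna().sum(axis=1) >= min_replicates
    return set(intensities.values.index[ok])


def ac4c_detected_genes(cons_peaks: list[ConsensusPeak]) -> set[str]:
    """Genes carrying at least one validated consensus peak in the group."""
    return {p.host_gene for p in cons_peaks if p.host_gene is not None}
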