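"""Bundled reference datasets."""

from importlib import resources

import pandas as pd


def load_reference_pair_counts() -> pd.DataFrame:
    """Replicate-pair call counts from a 17-sample duplicate/triplicate
    kinome capture sequencing study (one row per replicate pair).

    Columns: sample_id, replicate_type (dup/trp), pair, and concordant /
    mean-total counts for whole-region unambiguous consensus calls
    (``allcall_*``) and for SNV calls compared by genotype (``snv_*``).
    The totals are the printed mean of the two replicates' totals.
    """
    ref = resources.files("varconcord") / "data" / "replicate_pair_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#",
                           dtype={"sample_id": str})
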