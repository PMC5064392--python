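import numpy as np
import pytest

from gwas_efficiency.summary_io import LocusRecord, PairedLocus, StudyPanel


def make_record(locus_id="FTO", trait="BMI", n=100_000, p=None, neglog10_p=None, **kwargs):
    if neglog10_p is None:
        neglog10_p = -np.log10(p if p is not None else 1e-8)
    return LocusRecord(locus_id=locus_id, trait=trait, n=n, neglog10_p=float(neglog10_p), **kwargs)


def make_pair(n1=200_000, n2=100_000, p1=1e-10, p2=1e-6, locus_id="FTO"):
    return PairedLocus(
        locus_id=locus_id,
        larger=make_record(locus_id, n=n1, p=p1),
        smaller=make_record(locus_id, n=n2, p=p2),
        larger_study_label="study_a",
    )


@pytest.fixture
def toy_panels():
    """Two BMI panels sharing 4 of 5 loci; locus GIPR has the larger n in panel_b."""
    rec = make_record
    panel_a = StudyPanel(
        "giant_2015",
        "BMI",
        [
            rec("FTO", n=320_000, p=1e-60),
            rec("MC4R", n=318_000, p=1e-30),
            rec("TMEM18", n=315_000, p=1e-25),
            rec("GIPR", n=250_000, p=1e-10),
            rec("SEC16B", n=310_000, p=1e-12),
        ],
    )
    panel_b = StudyPanel(
        "giant_2010",
        "BMI",
        [
            rec("FTO", n=240_000, p=1e-50),
            rec("MC4R", n=240_000, p=1e-28),
            rec("TMEM18", n=239_000, p=1e-22),
            rec("GIPR", n=260_000, p=1e-11),
            rec("NEGR1", n=238_000, p=1e-9),
        ],
    )
    return panel_a, panel_b


def write_tsv(path, rows, header=("locus_id", "trait", "n", "p")):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
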