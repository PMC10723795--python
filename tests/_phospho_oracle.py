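"""Independent hand enumeration of the phosphosite filtering rules.

Builds a 50-row planted table spanning every pass/fail combination and
derives the expected surviving set by directly re-stating the published
rules, independently of the package implementation.
"""

from nucleoscore.phospho import PhosphoSiteRecord


def build_planted_records(rng):
    records = []
    expected = set()
    for i in range(50):
        protein = f"P{i:02d}"
        site = f"S{int(rng.integers(1, 999))}"
        untreated = tuple(int(x) for x in rng.integers(0, 7, 2))
        treated_a = tuple(int(x) for x in rng.integers(0, 5, 2))
        treated_b = tuple(int(x) for x in rng.integers(0, 5, 2))
        fdr_a = float(rng.choice([1e-6, 5e-5, 0.01, 0.5]))
        fdr_b = float(rng.choice([1e-6, 0.01, 0.5]))
        logfc_a = float(rng.choice([-2.5, -0.5, 0.5, 2.5]))
        logfc_b = float(rng.choice([-2.5, 0.5]))
        records.append(
            PhosphoSiteRecord(
                protein_id=protein,
                site=site,
                spectra_untreated=untreated,
                spectra_treated={"drugA": treated_a, "drugB": treated_b},
                protein_logfc={"drugA": logfc_a, "drugB": logfc_b},
                protein_fdr={"drugA": fdr_a, "drugB": fdr_b},
            )
        )
        # hand enumeration: each untreated replicate needs >= 2 spectra;
        # exclude sites on proteins significantly decreased (FDR < 1e-4
        # with negative LogFC) under either drug; drop evidence-free rows
        counts_ok = untreated[0] >= 2 and untreated[1] >= 2
        decreased_a = fdr_a < 1e-4 and logfc_a < 0
        decreased_b = fdr_b < 1e-4 and logfc_b < 0
        has_evidence = sum(untreated) > 0 or (
            sum(treated_a) > 0 and sum(treated_b) > 0
        )
        if counts_ok and not (decreased_a or decreased_b) and has_evidence:
            expected.add((protein, site))
    return records, expected
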