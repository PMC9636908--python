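import pytest

from bpscan.detection import VariantRecord, classify_variant
from bpscan.fixtures import FixtureBundle, build_validation_panel
from bpscan.io import trim_alleles
from bpscan.pipeline import DetectionRun, run_detection


def bundle_variants(bundle: FixtureBundle) -> list[VariantRecord]:
    """Build VariantRecords straight from a bundle's VCF rows."""
    records = []
    for chrom, pos, vid, ref, alt in bundle.vcf_rows:
        t_ref, t_alt, shift = trim_alleles(ref, alt)
        var_type, interval, is_complex = classify_variant(t_ref, t_alt, pos + shift)
        records.append(
            VariantRecord(
                contig=chrom,
                pos=pos + shift,
                id=vid,
                ref=t_ref,
                alt=t_alt,
                var_type=var_type,
                affected_interval=interval,
                complex_flag=is_complex,
            )
        )
    return records


def run_bundle(bundle: FixtureBundle, **kwargs) -> DetectionRun:
    return run_detection(
        bundle.genome,
        bundle.transcripts,
        bundle.bp_records(),
        bundle_variants(bundle),
        tracks=bundle.tracks or None,
        **kwargs,
    )


@pytest.fixture(scope="session")
def panel_bundle() -> FixtureBundle:
    return build_validation_panel(seed=1)


@pytest.fixture(scope="session")
def panel_run(panel_bundle) -> DetectionRun:
    return run_bundle(panel_bundle)
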