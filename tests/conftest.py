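import pytest

from mrpd.summary_io import HarmonisedVariant, VariantAssociation, load_fixture_table1


@pytest.fixture(scope="session")
def table1():
    return load_fixture_table1()


def hv(vid="rs1", bx=0.02, sx=0.003, by=-0.01, sy=0.017, eaf=0.4, **kw):
    """Shorthand harmonised-variant builder for tests."""
    return HarmonisedVariant(
        variant_id=vid, beta_zx=bx, se_zx=sx, beta_zy=by, se_zy=sy,
        eaf_exposure=eaf, **kw,
    )


def va(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.02, se=0.003, p=1e-9,
       chrom=None, pos=None):
    """Shorthand variant-association builder for tests."""
    return VariantAssociation(
        variant_id=vid, effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=beta, se=se, p_value=p, chromosome=chrom, position=pos,
    )
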