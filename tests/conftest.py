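import textwrap

import pytest

from breps.records import SequenceRecord


def make_record(
    accession="P00001",
    sequence="M" + "A" * 149,
    description="RecName: Full=Alcohol dehydrogenase; EC=1.1.1.1;",
    ecs=("1.1.1.1",),
    evidence_level=1,
    has_publication=True,
    source="seed",
):
    return SequenceRecord(
        accession=accession,
        sequence=sequence,
        description=description,
        ec_sets=(frozenset(ecs),) if ecs else (),
        evidence_level=evidence_level,
        has_publication=has_publication,
        source=source,
    )


@pytest.fixture
def record_factory():
    return make_record


FLATFILE = textwrap.dedent(
    """\
    ID   ADH1_SYN   Reviewed;   120 AA.
    AC   P00001; Q99999;
    DE   RecName: Full=Alcohol dehydrogenase; EC=1.1.1.1;
    PE   1: Evidence at protein level;
    RX   PubMed=123456;
    SQ   SEQUENCE   120 AA;  0 MW;  0 CRC64;
         MKAVLTGAAG QIGYALVPMI ARGIMLGADQ PVILHMLDIP PAAEALNGVK
         MELIDAAFPL LKGVVATTDA VEGCTGVNVA VMVGGFPRKE GMERKDVMSK
         NVSIYKSQAS ALEKHAAPNC
    //
    ID   ACCC_SYN   Reviewed;   120 AA.
    AC   P00002;
    DE   RecName: Full=Acetyl-CoA carboxylase; EC=6.4.1.2;
    DE   Includes: RecName: Full=Biotin carboxylase; EC=6.3.4.14;
    PE   1: Evidence at protein level;
    RX   PubMed=777;
    SQ   SEQUENCE   120 AA;  0 MW;  0 CRC64;
         MFEKVLIANR GEIALRILRA CKELGIKTVA VHSSADRDLK HVLLADETVC
         IGPAPSVKSY LNIPAIISAA EITGAVAIHP GYGFLSENAN FAEQVERSGF
         IFIGPKAETI RLMGDKVSAI
    //
    ID   PUTA_SYN   Reviewed;   120 AA.
    AC   P00003;
    DE   RecName: Full=Putative oxidoreductase; EC=1.1.1.2;
    PE   1: Evidence at protein level;
    RX   PubMed=1;
    SQ   SEQUENCE   120 AA;  0 MW;  0 CRC64;
         MKAVLTGAAG QIGYALVPMI ARGIMLGADQ PVILHMLDIP PAAEALNGVK
         MELIDAAFPL LKGVVATTDA VEGCTGVNVA VMVGGFPRKE GMERKDVMSK
         NVSIYKSQAS ALEKHAAPNC
    //
    ID   SHRT_SYN   Reviewed;   99 AA.
    AC   P00004;
    DE   RecName: Full=Short enzyme; EC=2.7.1.1;
    PE   1: Evidence at protein level;
    RX   PubMed=2;
    SQ   SEQUENCE   99 AA;  0 MW;  0 CRC64;
         MFEKVLIANR GEIALRILRA CKELGIKTVA VHSSADRDLK HVLLADETVC
         IGPAPSVKSY LNIPAIISAA EITGAVAIHP GYGFLSENAN FAEQVERSG
    //
    ID   PE2_SYN   Reviewed;   120 AA.
    AC   P00005;
    DE   RecName: Full=Homology-inferred enzyme; EC=3.1.1.3;
    PE   2: Evidence at transcript level;
    RX   PubMed=3;
    SQ   SEQUENCE   120 AA;  0 MW;  0 CRC64;
         MFEKVLIANR GEIALRILRA CKELGIKTVA VHSSADRDLK HVLLADETVC
         IGPAPSVKSY LNIPAIISAA EITGAVAIHP GYGFLSENAN FAEQVERSGF
         IFIGPKAETI RLMGDKVSAI
    //
    ID   NONE_SYN   Reviewed;   120 AA.
    AC   P00006;
    DE   SubName: Full=Uncharacterized protein;
    PE   1: Evidence at protein level;
    SQ   SEQUENCE   120 AA;  0 MW;  0 CRC64;
         MSTNPKPQRK TKRNTNRRPQ DVKFPGGGQI VGGVYLLPRR GPRLGVRATR
         KTSERSQPRG RRQPIPKARR PEGRTWAQPG YPWPLYGNEG CGWAGWLLSP
         RGSRPSWGPT DPRRRSRNLG
    //
    ID   BROKEN_SYN   Reviewed;   10 AA.
    AC   P00007;
    DE   RecName: Full=Broken record; EC=9.9.9.9;
    PE   1: Evidence at protein level;
    //
    """
)


@pytest.fixture
def flatfile_text():
    return FLATFILE
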