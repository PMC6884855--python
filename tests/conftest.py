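import pytest

from nanobarcoder.demux import Read
from nanobarcoder.pipeline import design_tagset
from nanobarcoder.simulate import (AnomalySpec, ClusterSpec, ErrorModel,
                                   build_truth, default_layout,
                                   make_templates, simulate_reads)

# COI barcode of Megaselia sepsioides (GenBank MN403533), 657 nt,
# translatable in frame 0 under the invertebrate mitochondrial code.
EXAMPLE_BARCODE = (
    "actttatattttatttttggagcttgagctggaatagtaggtacttccttaagaatcataattcgtgct"
    "gaattaggacacccaggagcacttattggtgatgaccaaatttataatgtgattgttactgcacatgct"
    "tttattataattttttttatagtaatacctattataataggaggttttggtaattgacttgtaccttta"
    "atattaggagccccagatatggcattccctcgaatgaataatataagtttttgaatattacctccttct"
    "ttaactcttttattagccagaagtatagtagaaaatggagctggaactggttgaacagtttatcctcct"
    "ttatcttctagaatcgctcatagtggagcttctgttgatttagcaattttctctcttcatttagctgga"
    "atttcatctattttaggagctgtaaattttattacaacaattattaatatacgatcatcaggtattaca"
    "tttgaccgaatacctctatttgtttgatctgtaggtattacagctttattgctactcttatcacttcct"
    "gttttagctggtgctattacaatactattaacagaccgaaattttaatacttcattttttgacccagca"
    "ggaggaggagatccaattttataccaacatttattc"
).upper()


@pytest.fixture(scope="session")
def example_barcode():
    return EXAMPLE_BARCODE


@pytest.fixture(scope="session")
def small_tagsets():
    """Validated small forward/reverse tag sets."""
    fwd = design_tagset(8, "forward", seed=1)
    rev = design_tagset(8, "reverse", seed=2, excluded_motif="")
    return fwd, rev


@pytest.fixture(scope="session")
def mini_run(small_tagsets):
    """A small simulated run with 12% error and known truth: 12 specimens
    (4 species x 3), coverage 40, with dimer/unused/cross anomalies."""
    fwd, rev = small_tagsets
    spec = ClusterSpec(n_species=4, specimens_per_species=3,
                       intra_max=0.01, inter_min=0.08)
    templates, labels = make_templates(spec, seed=5)
    layout = default_layout(12, fwd.sequences, rev.sequences)
    truth = build_truth(layout, templates, labels, [40] * 12)
    model = ErrorModel(seed=11)  # 12% total error, 60% indel share
    anomalies = AnomalySpec(fraction_ligated_dimers=0.02,
                            fraction_unused_tag_reads=0.01,
                            fraction_cross_contaminating_reads=0.005)
    raw, manifest = simulate_reads(truth, layout, model, anomalies,
                                   fwd.sequences, rev.sequences)
    reads = [Read(r, s) for r, s in raw]
    return {"fwd": fwd, "rev": rev, "layout": layout, "truth": truth,
            "reads": reads, "manifest": manifest,
            "library": {t.specimen_id: t.template for t in truth}}


@pytest.fixture(scope="session")
def zero_error_run(small_tagsets):
    """Same structure with error-free reads: every downstream stage must
    recover the truth exactly."""
    fwd, rev = small_tagsets
    spec = ClusterSpec(n_species=3, specimens_per_species=2)
    templates, labels = make_templates(spec, seed=9)
    layout = default_layout(6, fwd.sequences, rev.sequences)
    truth = build_truth(layout, templates, labels, [10] * 6)
    model = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0, seed=4)
    raw, manifest = simulate_reads(truth, layout, model)
    reads = [Read(r, s) for r, s in raw]
    return {"fwd": fwd, "rev": rev, "layout": layout, "truth": truth,
            "reads": reads, "manifest": manifest}
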