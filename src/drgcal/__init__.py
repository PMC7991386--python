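"""Unsupervised extraction of GCaMP6f responses from wide-field DRG recordings.

The package implements a post-processing chain for calcium-imaging stacks of
intact dorsal root ganglia: rigid motion correction by mutual-information
maximization, iterative watershed-based detection of active somata on the
temporal-variance map, ΔF/F trace extraction and zero-phase band-pass
filtering, calcium-transient detection with an amplitude/rise-time criterion,
and functional classification of colorectal afferents from their responses to
graded luminal distension and mucosal shear flow.

A synthetic-recording generator (:mod:`drgcal.synthgen`) produces stacks with
complete ground truth — soma masks, spike trains, motion trajectories and
class labels — so the whole chain is testable without experimental data.
"""

from drgcal._version import __version__
from drgcal.io_stack import ImageStack, load_stack, save_stack, export_traces
from drgcal.registration import (
    RigidTransform,
    AlignmentResult,
    RegistrationSettings,
    mutual_information,
    register_pair,
    align_stack,
)
from drgcal.detection import (
    DetectionParams,
    VarianceMap,
    LabelMap,
    NeuronROI,
    variance_map,
    dual_threshold,
    morph_close_open,
    remove_small_and_border,
    watershed_labels,
    select_by_size,
    detect_neurons,
)
from drgcal.traces import (
    Trace,
    TransientEvent,
    extract_traces,
    normalize_dff,
    spectrum,
    bandpass,
    detect_transients,
    single_spike_resolvable,
)
from drgcal.classify import (
    StimulusProtocol,
    DistensionStep,
    ShearWindow,
    ResponseProfile,
    AfferentClass,
    build_profile,
    classify_afferent,
    class_summary,
)
from drgcal.synthgen import SynthConfig, GroundTruth, sample_geometry, spikes_from_class, render_recording
from drgcal.pipeline import PipelineConfig, run_pipeline

__all__ = [
    "ImageStack", "load_stack", "save_stack", "export_traces",
    "RigidTransform", "AlignmentResult", "RegistrationSettings",
    "mutual_information", "register_pair", "align_stack",
    "DetectionParams", "VarianceMap", "LabelMap", "NeuronROI",
    "variance_map", "dual_threshold", "morph_close_open",
    "remove_small_and_border", "watershed_labels", "select_by_size",
    "detect_neurons",
    "Trace", "TransientEvent", "extract_traces", "normalize_dff",
    "spectrum", "bandpass", "detect_transients", "single_spike_resolvable",
    "StimulusProtocol", "DistensionStep", "ShearWindow", "ResponseProfile",
    "AfferentClass", "build_profile", "classify_afferent", "class_summary",
    "SynthConfig", "GroundTruth", "sample_geometry", "spikes_from_class",
    "render_recording",
    "PipelineConfig", "run_pipeline",
]
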