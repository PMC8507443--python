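"""End-to-end bone segmentation: the five pipeline stages chained.

1. histogram matching to a reference + patient-table removal,
2. dual-threshold segmentation (bone + seed masks),
3. seeded 3D region growing (26-connectivity, precomputed criteria),
4. union of region-growing and threshold results,
5. merging of close bone parts and 3D interior filling (marrow).
"""

from __future__ import annotations

import logging
from contextlib import contextmanager

from .errors import PipelineStageError
from .holefill import fill_interior_2d_baseline, fill_interior_3d, merge_close_parts
from .preprocessing import ReferenceHistogram, default_reference, match_histogram, \
    remove_table
from .segmentation import PipelineParams, combine_masks, local_maximum_mask, \
    region_grow, threshold_segment
from .volumes import CTVolume, LabelVolume

log = logging.getLogger("pelviseg")


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_pipeline(vol: CTVolume, params: PipelineParams | None = None,
                 ref: ReferenceHistogram | None = None,
                 holefill: str = "3d",
                 table_removal: bool = True) -> LabelVolume:
    """Run the full segmentation on a CT volume.

    Parameters
    ----------
    vol:
        Input CT volume in HU.
    params:
        Pipeline parameters; defaults to :class:`PipelineParams()`.
    ref:
        Reference histogram for intensity matching; the packaged default is
        used when omitted.
    holefill:
        ``"3d"`` (default) or ``"2d"`` for the slice-wise baseline.
    table_removal:
        Disable to skip body-component extraction (e.g. for phantoms known
        to contain no table).

    Returns the label volume (0 background, 1 compact bone, 2 interior
    /marrow).  Deterministic: identical inputs give bit-identical output.
    Errors raised in any stage are re-raised as
    :class:`~pelviseg.errors.PipelineStageError` naming the stage.
    """
    params = params if params is not None else PipelineParams()
    params.validate()
    if holefill not in ("3d", "2d"):
        raise PipelineStageError("holefill", ValueError(f"unknown mode '{holefill}'"))

    with _stage("match_histogram"):
        if ref is None:
            ref = default_reference()
        matched = match_histogram(vol, ref, air_threshold=params.air_threshold)
        log.info("match_histogram: reference '%s'", ref.source_id)

    if table_removal:
        with _stage("remove_table"):
            matched, _body = remove_table(matched, air_threshold=params.air_threshold)

    with _stage("threshold_segment"):
        bone_mask, seed_mask = threshold_segment(matched, params)

    with _stage("local_maximum_mask"):
        lmax = local_maximum_mask(matched, params.box_n)

    with _stage("region_grow"):
        grown = region_grow(matched, seed_mask, lmax, params)

    with _stage("combine_masks"):
        combined = combine_masks(grown, bone_mask)
        log.info("combine_masks: %d voxels", combined.count())

    with _stage("merge_close_parts"):
        merged = merge_close_parts(combined, params.merge_radius_mm)

    with _stage("fill_interior"):
        if holefill == "3d":
            labels = fill_interior_3d(merged)
        else:
            labels = fill_interior_2d_baseline(merged)

    return labels
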