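"""Reference per-video summary tables from a three-experiment bean study.

These are the per-video, per-view detection-type counts and reprojection
statistics reported for three stereo time-lapse recordings of climbing
common-bean plants (video pairs 4, 7 and 10; pair 7 was recorded both with
and without a support pole). They are bundled as *inputs* so that the
study-level aggregate statistics — overall mean reprojection error, the
fraction of points above the 10 px flag threshold, and the fraction of
frames needing manual correction — can be recomputed with
:func:`circumtrack.reconstruction.summarize_tables`.

Note: the "pair7_pole" detection rows sum to 2225 frames although the
quoted frame range 3850-5798 spans 1949; this inconsistency is in the
source material and is preserved as-is.
"""
from .reconstruction import DetectionCounts, VideoReprojectionSummary

FLAG_THRESHOLD_PX = 10.0

# columns: video, view, frame_start, frame_end,
#          automatic, manual, estimated, interpolated
DETECTION_TABLE = [
    DetectionCounts("pair4_nopole", "side", 2483, 4746, 1586, 331, 293, 54),
    DetectionCounts("pair4_nopole", "top", 2483, 4746, 1878, 74, 265, 47),
    DetectionCounts("pair7_pole", "side", 3850, 5798, 1607, 272, 246, 100),
    DetectionCounts("pair7_pole", "top", 3850, 5798, 2063, 27, 113, 22),
    DetectionCounts("pair7_nopole", "side", 750, 2600, 1285, 208, 287, 71),
    DetectionCounts("pair7_nopole", "top", 750, 2600, 1724, 53, 74, 0),
    DetectionCounts("pair10_nopole", "side", 3850, 5798, 1353, 251, 236, 109),
    DetectionCounts("pair10_nopole", "top", 3850, 5798, 1570, 151, 209, 19),
]

# columns: video, view, mean RE (px), stdev RE (px), total points,
#          points with RE > 10 px
REPROJECTION_TABLE = [
    VideoReprojectionSummary("pair4_nopole", "side", 3.98679, 2.84289, 2264, 39),
    VideoReprojectionSummary("pair4_nopole", "top", 6.49004, 5.74389, 2264, 373),
    VideoReprojectionSummary("pair7_nopole", "side", 2.05453, 2.52104, 1851, 33),
    VideoReprojectionSummary("pair7_nopole", "top", 2.66366, 3.13255, 1851, 47),
    VideoReprojectionSummary("pair10_nopole", "side", 2.99391, 2.62791, 1949, 41),
    VideoReprojectionSummary("pair10_nopole", "top", 4.08886, 3.31717, 1949, 119),
]

# stereo-system calibration residuals (px) for the two recording scenarios:
# (mean top, stdev top, mean side, stdev side, mean stereo, stdev stereo)
CALIBRATION_TABLE = {
    "no_pole": (0.47202, 0.34563, 0.29831, 0.27472, 0.61930, 0.55591),
    "pole": (0.30597, 0.20053, 0.28490, 0.18405, 0.91065, 0.80017),
}

IMAGE_WIDTH_PX = 1280
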