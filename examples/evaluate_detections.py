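"""Walk through the detection metrics on a tiny hand-made example.

Two ground-truth boxes and three detections: a confident hit, a false
positive, and a late hit. The 101-point interpolated average precision of
this sweep is (51*1 + 50*(2/3))/101 ~ 0.835.
"""

from organodet import Detection, GroundTruth, average_precision, confusion_matrix, iou

gts = {0: [GroundTruth((0, 0, 10, 10), 0), GroundTruth((20, 20, 30, 30), 0)]}
dets = {0: [Detection((0, 0, 10, 10), 0, 0.9),      # true positive
            Detection((50, 50, 60, 60), 0, 0.8),    # false positive
            Detection((20, 20, 30, 30), 0, 0.7)]}   # true positive

print(f"IoU of the overlapping pair (0,0,10,10)/(5,5,15,15): "
      f"{iou((0, 0, 10, 10), (5, 5, 15, 15)):.6f}  (= 25/175)")
ap = average_precision(dets, gts, iou_thr=0.5)
print(f"AP@0.5 of the three-detection sweep: {ap:.4f}  (expected 0.8350)")

cm = confusion_matrix(dets, gts, n_classes=1, iou_thr=0.5, score_thr=0.5)
print("confusion counts (rows: gt class then background; cols: same):")
print(cm.counts)
# Row 0: both gts matched to class-0 detections; row 1 (background):
# the unmatched false positive.
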