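# Core module catalog: module_name:dotted.path.to.operation
# Input/Output
input:voxpipe.ops.op_input
save:voxpipe.ops.op_save
output:voxpipe.ops.op_output
attach:voxpipe.ops.op_attach
deleteList:voxpipe.ops.op_deleteList
# Calibration
calibration:voxpipe.ops.op_calibration
saveCalibration:voxpipe.ops.op_saveCalibration
loadCalibration:voxpipe.ops.op_loadCalibration
# Processing
crop:voxpipe.ops.op_crop
math:voxpipe.ops.op_math
scale:voxpipe.ops.op_scale
# Filtering
filters:voxpipe.ops.op_filters
# Thresholding
autoThreshold:voxpipe.ops.op_autoThreshold
threshold:voxpipe.ops.op_threshold
percentile:voxpipe.ops.op_percentile
hysteresis:voxpipe.ops.op_hysteresis
# Labelling
label:voxpipe.ops.op_label
# Post-processing
fillHoles:voxpipe.ops.op_fillHoles
closing:voxpipe.ops.op_closing
excludeEdges:voxpipe.ops.op_excludeEdges
keepBiggest:voxpipe.ops.op_keepBiggest
filterSize:voxpipe.ops.op_filterSize
filterShape:voxpipe.ops.op_filterShape
# Analysis
measurement:voxpipe.ops.op_measurement
quantification:voxpipe.ops.op_quantification
coloc:voxpipe.ops.op_coloc
numbering:voxpipe.ops.op_numbering
distances:voxpipe.ops.op_distances
# Measurements processing
mergeTables:voxpipe.ops.op_mergeTables
appendTables:voxpipe.ops.op_appendTables
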