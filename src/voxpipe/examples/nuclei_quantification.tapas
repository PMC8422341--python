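// Segment nuclei in channel 1, quantify channel-2 intensity inside them,
// and attach both results tables to the source image.

// load channel 2 and save it to the work folder for later quantification
process : input
channel : 2

// ?image? expands to the name of the image being processed
process : save
dir : ?ij?
file : ?image?-C2

// load the segmentation channel
process : input
channel : 1

// 3D median filtering
process : filters
radiusXY : 4
radiusZ : 2

// automatic global thresholding
process : autoThreshold
method : Otsu

// connected components, discarding small ones
process : label
minSize : 100

// drop objects touching the XY borders
process : excludeEdges

// store the labelled nuclei back into the database
process : output
image : ?image?-nuclei

// geometry and shape per nucleus, saved to the work folder first
process : measurement
list : volume, compactness
dir : ?ij?
file : ?image?-nuclei-measurements.csv

// link the measurements to the source image
process : attach
dir : ?ij?
file : ?image?-nuclei-measurements.csv

// per-nucleus intensity statistics over the saved raw channel 2
process : quantification
dirRaw : ?ij?
fileRaw : ?image?-C2
list : mean, sum
dir : ?ij?
file : ?image?-nuclei-quantification.csv

// link the quantification table to the source image
process : attach
dir : ?ij?
file : ?image?-nuclei-quantification.csv

// clean up the work folder
Process : deleteList
dir : ?ij?
list :  ?image?-C2, ?image?-nuclei-measurements.csv, ?image?-nuclei-quantification.csv
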