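id	taxon	status	required_elements	description
D1	Diamantinasaurus	autapomorphy	dorsal_vertebra	Middle-posterior dorsal vertebrae with dorsally bifurcated PCPL
D2	Diamantinasaurus	local_autapomorphy	scapula	Scapula medial surface with tuberosity posterior to acromion & distal blade junction
D3	Diamantinasaurus	autapomorphy	humerus	Humerus proximal shaft posterolateral margin with vertical ridge that increases depth of lateral triceps fossa
D4	Diamantinasaurus	autapomorphy	humerus	Humerus ridge extending medially from deltopectoral crest, then proximally, creating fossa medial to dorsal part of deltopectoral crest on anterior face
D5	Diamantinasaurus	autapomorphy	tibia	Tibia proximal lateral face with double ridge extending distally from lateral projection of proximal articular area
D6	Diamantinasaurus	autapomorphy	tibia	Tibia with posterolateral fossa posterior to double ridge, with lower tuberosity & upper deep pit
D7	Diamantinasaurus	autapomorphy	tibia	Tibia shaft anterolateral margin, distal to cnemial crest, forms thin projection proximodistally along central region of element
D8	Diamantinasaurus	autapomorphy	astragalus	Astragalus posteroventral margin, ventral & medial to ascending process, with ventrally projecting rounded process visible in posterior, lateral & ventral views
S1	Savannasaurus	autapomorphy	caudal_vertebra	Undulating anterior articular surface of anterior caudal vertebral centra
S2	Savannasaurus	local_autapomorphy	caudal_vertebra	Anterior-most caudal centra with shallow lateral pneumatic fossae
S3	Savannasaurus	autapomorphy	sternal_plate	Sternal plate with straight lateral margin
S4	Savannasaurus	local_autapomorphy	sternal_plate	Sternal plate lacking anteroposteriorly elongate ridge along anterior portion of ventral surface
S5	Savannasaurus	autapomorphy	metacarpal_IV	Metacarpal IV distal end hourglass-shaped
S6	Savannasaurus	autapomorphy	pubis	Pubis with ridge extending anteroventrally from ventral margin of obturator foramen on lateral surface
S7	Savannasaurus	autapomorphy	ischium	Ischium with proximal plate anteroposterior length >40% overall proximodistal length of element
S8	Savannasaurus	autapomorphy	astragalus	Astragalus taller proximodistally than wide mediolaterally or long anteroposteriorly
S9	Savannasaurus	autapomorphy	astragalus	Astragalus mediolateral width & anteroposterior length essentially equal
W1	Wintonotitan	autapomorphy	dorsal_vertebra	Median ridge on dorsal vertebra neural spine summit linking PRSL & POSL
W2	Wintonotitan	autapomorphy	caudal_vertebra	Anterior-middle caudal centra with horizontal ridge at mid-height
W3	Wintonotitan	local_autapomorphy	caudal_vertebra	Middle-posterior caudal vertebrae neural arches only slightly anteriorly biased
W4	Wintonotitan	local_autapomorphy	caudal_vertebra	Posterior caudal vertebrae articular surfaces incipiently biconvex
W5	Wintonotitan	autapomorphy	scapula	Scapular blade with fossa on medial surface close to acromion-distal blade junction
W6	Wintonotitan	autapomorphy	metacarpal_III	Metacarpal III with distal end more expanded transversely than proximal end
W7	Wintonotitan	autapomorphy	metacarpal_IV	Metacarpal IV with medially projecting bulge on dorsal surface, close to shaft mid-length
W8	Wintonotitan	local_autapomorphy	ischium	Ischium with posterolaterally projecting flange-like ridge for M. flexor tibialis internus III, visible in medial view
A1	Australotitan	synapomorphy_candidate	ulna	Ulna with prominent interosseous ridge on distal anterior surface (probable clade synapomorphy)
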