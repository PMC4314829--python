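code,dhqase_type,origin,ncbi_accession,sbb_accession,mass_kda,identity_pct
3002,I,Escherichia coli,YP_489955.1,SBB_00449,27.5,100.0
3029,I,Staphylococcus aureus,YP_005744190.1,SBB_00476,26.9,30.0
3030,I,Metallosphaera cuprina,YP_004409005.1,SBB_00477,23.7,23.5
3001,II,Corynebacterium glutamicum,YP_224725.1,SBB_00448,15.4,100.0
3003,II,Alcanivorax borkumensis,YP_693728.1,SBB_00450,17.5,50.7
3004,II,Bacillus pseudofirmus,YP_003425282.1,SBB_00451,16.5,50.0
3005,II,Citrobacter koseri,YP_001456151.1,SBB_00452,16.5,53.4
3006,II,Enterobacter aerogenes,YP_004591144.1,SBB_00453,16.5,53.0
3007,II,Gluconobacter oxydans,YP_190876.1,SBB_00454,17.4,51.1
3008,II,Mycobacterium tuberculosis,YP_003031384.1,SBB_00455,15.8,52.6
3009,II,Psychrobacter sp. PRwf-1,YP_001279670.1,SBB_00456,18.4,52.8
3010,II,Psychromonas ingrahamii,YP_944417.1,SBB_00457,16.5,53.0
3011,II,Xylella fastidiosa,NP_297340.2,SBB_00458,16.7,52.2
3012,II,Arthrobacter crystallopoietes,EMY34512.1,SBB_00459,16.3,71.9
3013,II,Micromonas poralupini,CCH17589.1,SBB_00460,15.4,47.8
3014,II,Nocardia brasiliensis,YP_006813099.1,SBB_00461,15.6,64.0
3015,II,Propionibacterium acnes,YP_056375.1,SBB_00462,15.8,43.7
3016,II,Streptomyces acidiscabies,WP_010352491.1,SBB_00463,16.8,61.4
3017,II,Thermomonas poracurvata,YP_003300530.1,SBB_00464,16.6,45.3
3018,II,Atopobium rimae,EEE18006.1,SBB_00465,15.5,41.7
3019,II,Acidimicrobium ferrooxidans,YP_003110305.1,SBB_00466,16.4,45.8
3020,II,Bacillus subtilis,NP_390327.1,SBB_00467,16.4,49.3
3021,II,Geobacillus sp. Y4.1MC1,YP_003988579.1,SBB_00468,16.0,48.6
3022,II,Alicyclobacillus acidocaldarius,EED07485.1,SBB_00469,16.3,49.6
3023,II,Butyrivibrio crossotus,EFF68279.1,SBB_00470,22.8,47.1
3024,II,Halanaerobium hydrogeniformans,YP_003995185.1,SBB_00471,16.6,51.4
3025,II,Clostridium clariflavum,YP_005045936.1,SBB_00472,15.5,53.1
3026,II,Natranaerobius thermophilus,YP_001917881.1,SBB_00473,15.8,43.7
3027,II,Ruminococcus champanellensis,YP_007829441.1,SBB_00474,16.1,49.6
3028,II,Thermodesulfobium narugense,YP_004438087.1,SBB_00475,16.8,46.3
3031,II,Comamonas testosteroni,YP_003279351.1,SBB_00478,15.9,52.1
3032,II,Pseudomonas putida,NP_745147.1,SBB_00479,16.2,59.4
3033,II,Halomonas elongata,YP_003899044.1,SBB_00480,15.5,55.8
3034,II,Vibrio vulnificus,NP_935927.1,SBB_00481,18.7,55.6
3035,II,Acidithiobacillus caldus,YP_004750222.1,SBB_00482,16.9,50.7
3036,II,Klebsiella pneumoniae,EMH96211.1,SBB_00483,16.5,51.5
3037,II,Magnetospirillum magneticum,YP_422069.1,SBB_00484,14.5,50.4
3038,II,Zymomonas mobilis,YP_162472.1,SBB_00485,15.8,52.9
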