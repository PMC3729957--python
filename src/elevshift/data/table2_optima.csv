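species,south_optimum,south_ci_low,south_ci_high,south_pct_deviance,south_n_sites,north_optimum,north_ci_low,north_ci_high,north_pct_deviance,north_n_sites,shift
Brown Cuckoo-Dove,556.42,500.11,626.65,4.58,71,745.43,704.53,794.6,13.62,54,189.01
Topknot Pigeon,755.82,703.13,807.57,28.08,14,659.13,480.95,894.68,22.61,13,-96.69
Sulphur-crested Cockatoo,535.7,478.53,602.32,9.37,70,491.11,450.25,525.77,21.21,54,-44.59
Shining Bronze-Cuckoo,725.89,668.78,798.89,20.97,17,798.29,784.34,811.87,55.84,17,72.41
Rainbow Bee-eater,348.72,309.52,388.31,27.92,16,429.61,371.15,484.67,25.33,24,80.89
White-throated Treecreeper,951.07,903.05,1017.74,55.09,59,805.61,790.33,821.01,65.81,36,-145.45
Brown Gerygone,635.57,599.21,679.4,41.29,83,582.04,523.84,644.98,36.76,39,-53.53
Fernwren,797.9,754.45,857.1,44.25,53,978.51,893.4,1141.81,39.32,52,180.62
Mountain Thornbill,1193.13,1058.76,2012.18,50.1,27,1147.9,1057.8,1342.12,67.65,38,-45.22
Yellow-throated Scrubwren,766.26,717.21,828.29,42.98,36,795.99,727.65,879.9,42.88,38,29.73
Bridled Honeyeater,872.82,786.15,1055.37,32.76,45,1144.35,965.01,1951.55,33.5,49,271.53
Eastern Spinebill,932.17,815.44,1260.22,26.38,32,945.68,915.27,981.43,55.75,34,13.51
Lewin's Honeyeater,723.76,712.24,735.46,67.25,62,820.84,810.19,831.45,71.7,34,97.08
Scarlet Honeyeater,130.17,-267.66,227.96,24.29,13,654.74,638.87,670.66,58.62,10,524.56
Chowchilla,721.51,671.98,791.43,25.97,74,894.38,862.27,933.41,45.27,52,172.87
Eastern Whipbird,576.54,504.67,682.32,3.56,91,909.67,889.55,932.19,58.48,49,333.12
Bowers Shrike-Thrush,886.75,779.13,1148.02,28.25,45,897.83,878.63,918.44,61.54,38,11.08
Golden Whistler,782.59,747.19,827.37,49.59,64,900.9,862.67,948.43,54.38,47,118.3
Grey Fantail,698.33,606.43,904.9,15.03,69,756.21,699.47,830.69,21.45,62,57.88
Spectacled Monarch,113.6,-960.32,278.8,25.16,84,358.78,51.12,472.19,21.3,68,245.18
White-eared Monarch,403.93,348,453.38,15.09,20,274.53,-1215.35,444.97,8.99,16,-129.4
Victoria's Riflebird,498.89,460.16,537.84,8.85,75,579.32,554.55,603.08,24.08,61,80.43
Satin Bowerbird,887.38,809.23,1117.58,26.94,16,865.77,662.6,2324.39,16.04,7,-21.61
Spotted Catbird,550.98,506.72,602.58,15.08,82,642.76,601.6,684.24,17.71,71,91.78
Tooth-billed Bowerbird,799.01,762.65,849.06,35.7,27,881.9,851.07,915.79,47.74,28,82.89
Silvereye,262.54,-61.84,360,19.6,73,525.41,472.2,575.61,39.8,61,262.87
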