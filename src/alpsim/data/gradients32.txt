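# 32 unit gradient directions (electrostatic-repulsion point set), one per row: gx gy gz
-0.3302395810 -0.9395820876 0.0901516487
0.6633028530 0.7383513121 0.1219289347
-0.0480620743 0.9896517568 0.1352014695
0.5385400183 -0.8315998277 0.1357069464
-0.9364409248 -0.3105404493 0.1632269085
0.9772040716 -0.0705219173 0.2002470014
0.8435266644 -0.4959656063 0.2061089123
-0.7974674132 0.5564076882 0.2333585425
-0.9604879965 0.1413299210 0.2397679337
0.8839110856 0.3919058600 0.2551685515
-0.4327261612 0.8570279273 0.2797341618
0.1325609153 -0.9394506455 0.3160064689
-0.6825168712 -0.6515120611 0.3312140618
0.3106619035 0.8577718704 0.4095321721
-0.2778899355 -0.8136059679 0.5107078546
0.4926797991 -0.6737461818 0.5507564780
-0.7878934884 -0.2213642549 0.5746492126
0.5866662222 0.5517783747 0.5927591155
0.7949807151 0.1222621896 0.5941865192
-0.0900158896 0.7908265890 0.6053845437
0.7342038253 -0.3026578714 0.6077359261
-0.5216565316 0.5873842569 0.6187521295
-0.7407771178 0.2184015070 0.6352558882
0.0859819487 -0.6808785467 0.7273317738
-0.4702883022 -0.4843676476 0.7377105765
0.2014427891 0.5266111796 0.8258943445
0.4661653199 0.1406152664 0.8734513388
0.3653954111 -0.3100244089 0.8777078440
-0.2451996073 0.3919157110 0.8867238736
-0.4496823754 -0.0220858245 0.8929154370
-0.1016039968 -0.3370485979 0.9359887128
0.0452944705 0.0756067656 0.9961084419
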