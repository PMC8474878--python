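patient,gender,age,n_seizures,n_leading_seizures,interictal_hours
Pat1,Male,36,11,11,68.9
Pat2,Female,46,8,8,114.9
Pat3,Male,41,8,8,96.3
Pat4,Female,67,5,5,126
Pat5,Female,52,8,8,204.1
Pat6,Male,65,8,7,92.2
Pat7,Male,36,5,5,75.7
Pat8,Male,26,22,11,65.6
Pat9,Male,47,6,6,51.1
Pat10,Male,44,11,11,60.7
Pat11,Male,48,14,14,57.8
Pat12,Male,28,9,9,94.1
Pat13,Male,46,8,8,101.3
Pat14,Female,62,6,6,115.7
Pat15,Female,41,5,5,82.8
Pat16,Female,15,6,6,51.1
Pat17,Female,17,9,9,82.4
Pat18,Male,47,7,6,133
Pat19,Male,32,22,21,75.4
Pat20,Male,47,7,7,115.3
Pat21,Female,31,8,8,106.6
Pat22,Male,38,7,7,88.2
Pat23,Male,50,9,9,179.6
Pat24,Female,54,10,10,36.2
Pat25,Male,42,8,8,109.8
Pat26,Male,13,9,9,97.1
Pat27,Male,58,9,8,99.9
Pat28,Female,35,9,9,95.2
Pat29,Male,50,10,10,111.9
Pat30,Female,16,12,12,92.5
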