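manufacturer,model,component,size_id,ML,AP
Zimmer Biomet,NexGen,femur,B,58,50
Zimmer Biomet,NexGen,femur,C,64,54.5
Zimmer Biomet,NexGen,femur,D,68,58
Zimmer Biomet,NexGen,femur,E,72,62
Zimmer Biomet,NexGen,femur,F,76,66
DePuy,Sigma,femur,1.5,57,53
DePuy,Sigma,femur,2,60,56
DePuy,Sigma,femur,2.5,63,58
DePuy,Sigma,femur,3,66,61
DePuy,Sigma,femur,4,71,65
DePuy,Sigma,femur,5,73,69
Smith & Nephew,Legion,femur,2,58,50
Smith & Nephew,Legion,femur,3,62,55
Smith & Nephew,Legion,femur,4,66,59
Smith & Nephew,Legion,femur,5,70,62
Smith & Nephew,Legion,femur,6,73,66
Smith & Nephew,Legion,femur,7,77,70
Smith & Nephew,Legion,femur,8,80,75
Maxx Orthopedics,Freedom,femur,A,54,51
Maxx Orthopedics,Freedom,femur,B,58,54
Maxx Orthopedics,Freedom,femur,C,62,58
Maxx Orthopedics,Freedom,femur,D,64,60
Maxx Orthopedics,Freedom,femur,E,66,62
Maxx Orthopedics,Freedom,femur,F,70,66
Maxx Orthopedics,Freedom,femur,G,74,70
Maxx Orthopedics,Freedom,femur,H,78,74
Stryker,Scorpio,femur,3,57,51
Stryker,Scorpio,femur,4,60,54
Stryker,Scorpio,femur,5,62,56
Stryker,Scorpio,femur,6,65,58
Stryker,Scorpio,femur,7,67,61
Stryker,Scorpio,femur,8,70,63
Stryker,Scorpio,femur,9,72,65
Stryker,Scorpio,femur,11,77,70
Stryker,Scorpio,femur,13,82,75
Zimmer Biomet,NexGen,tibia,1,56,41
Zimmer Biomet,NexGen,tibia,2,62,41
Zimmer Biomet,NexGen,tibia,3,67,46
Zimmer Biomet,NexGen,tibia,4,70,46
Zimmer Biomet,NexGen,tibia,5,74,50
Zimmer Biomet,NexGen,tibia,6,77,50
DePuy,Sigma,tibia,1,59.2,39
DePuy,Sigma,tibia,1.5,61.8,40.7
DePuy,Sigma,tibia,2,64.6,42.6
DePuy,Sigma,tibia,2.5,67.1,44.2
DePuy,Sigma,tibia,3,69.6,45.8
DePuy,Sigma,tibia,4,74.9,49.3
DePuy,Sigma,tibia,5,80.6,53.1
DePuy,Sigma,tibia,6,86.8,57.2
Smith & Nephew,Legion,tibia,1,60,42
Smith & Nephew,Legion,tibia,2,64,45
Smith & Nephew,Legion,tibia,3,68,48
Smith & Nephew,Legion,tibia,4,71,50
Smith & Nephew,Legion,tibia,5,74,52
Smith & Nephew,Legion,tibia,6,77,54
Smith & Nephew,Legion,tibia,7,81,56
Smith & Nephew,Legion,tibia,8,85,59
Maxx Orthopedics,Freedom,tibia,1,59,40
Maxx Orthopedics,Freedom,tibia,2,62,40
Maxx Orthopedics,Freedom,tibia,3,66,42
Maxx Orthopedics,Freedom,tibia,4,66,46
Maxx Orthopedics,Freedom,tibia,5,71,48
Maxx Orthopedics,Freedom,tibia,6,72,50
Maxx Orthopedics,Freedom,tibia,7,76,52
Maxx Orthopedics,Freedom,tibia,8,78,54
Stryker,Scorpio,tibia,3,61,40
Stryker,Scorpio,tibia,4,63,42
Stryker,Scorpio,tibia,5,66,44
Stryker,Scorpio,tibia,6,68,45
Stryker,Scorpio,tibia,7,71,47
Stryker,Scorpio,tibia,9,77,51
Stryker,Scorpio,tibia,11,82,54
Stryker,Scorpio,tibia,13,88,58
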